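"""Simplicial meshes and piecewise-linear (P1) finite-element geometry.

A :class:`SimplexMesh` is a triangle (2D) or tetrahedron (3D) mesh with
per-element tissue labels and per-boundary-facet electrode labels.  All
quantities are SI: coordinates in metres, areas in m^2, volumes in m^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = ["SimplexMesh", "p1_interpolation_matrix", "write_vtk"]


@dataclass
class SimplexMesh:
    """Triangle/tetrahedron mesh with tissue and electrode labels.

    Parameters
    ----------
    nodes : (n_nodes, dim) float array
        Node coordinates in metres.
    elements : (n_elements, dim+1) int array
        Element connectivity.
    boundary_facets : (n_facets, dim) int array
        Facets (edges in 2D, triangles in 3D) on the domain boundary.
    element_tissue : (n_elements,) int array
        Index into ``tissue_names`` for every element.
    tissue_names : list of str
        Tissue label per index, e.g. ``["scalp", "skull", "csf", "brain"]``.
        Hemorrhage shells carry labels ``"hemorrhage:<diam>"``.
    facet_electrode : (n_facets,) int array
        Electrode label per boundary facet, 0 meaning "no electrode" and
        1..L the electrode number.
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_facets: np.ndarray
    element_tissue: np.ndarray
    tissue_names: list[str]
    facet_electrode: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # ------------------------------------------------------------------ basic
    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_electrodes(self) -> int:
        return int(self.facet_electrode.max(initial=0))

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        if self.elements.shape[1] != self.dim + 1:
            raise ValueError("element connectivity does not match dimension")
        if np.any(self.element_volumes() <= 0):
            raise ValueError("mesh contains degenerate (zero-volume) elements")
        L = self.n_electrodes
        for ell in range(1, L + 1):
            if not np.any(self.facet_electrode == ell):
                raise ValueError(f"electrode {ell} owns no boundary facet")

    # --------------------------------------------------------------- geometry
    def _edge_matrices(self) -> np.ndarray:
        """(n_el, dim, dim) matrices of edge vectors x_i - x_0, i=1..dim."""
        if "edge" not in self._cache:
            x = self.nodes[self.elements]  # (m, d+1, d)
            self._cache["edge"] = x[:, 1:, :] - x[:, :1, :]
            # note rows are edge vectors: A[e, i-1, :] = x_i - x_0
        return self._cache["edge"]

    def element_volumes(self) -> np.ndarray:
        """Element areas (2D) or volumes (3D)."""
        if "vol" not in self._cache:
            A = self._edge_matrices()
            det = np.linalg.det(A)
            fact = 2.0 if self.dim == 2 else 6.0
            self._cache["vol"] = np.abs(det) / fact
        return self._cache["vol"]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def barycentric_gradients(self) -> np.ndarray:
        """(n_el, dim+1, dim) gradients of the P1 basis on each element."""
        if "bgrad" not in self._cache:
            A = self._edge_matrices()  # rows x_i - x_0
            Ainv = np.linalg.inv(A)  # columns are grad lambda_i, i=1..d
            g = np.transpose(Ainv, (0, 2, 1))  # (m, d, d): row i-1 = grad λ_i
            g0 = -g.sum(axis=1, keepdims=True)
            self._cache["bgrad"] = np.concatenate([g0, g], axis=1)
        return self._cache["bgrad"]

    def gradient_operator(self) -> sp.csr_matrix:
        """Sparse operator D mapping nodal values to stacked element gradients.

        ``(D v).reshape(n_elements, dim)`` gives the (constant) gradient of
        the P1 interpolant of ``v`` on every element.
        """
        if "D" not in self._cache:
            m, d = self.n_elements, self.dim
            g = self.barycentric_gradients()  # (m, d+1, d)
            rows = np.broadcast_to(
                np.arange(m)[:, None, None] * d + np.arange(d)[None, None, :],
                (m, d + 1, d),
            )
            cols = np.broadcast_to(self.elements[:, :, None], (m, d + 1, d))
            D = sp.coo_matrix(
                (g.ravel(), (rows.ravel(), cols.ravel())),
                shape=(m * d, self.n_nodes),
            )
            self._cache["D"] = D.tocsr()
        return self._cache["D"]

    def element_gradients(self, nodal: np.ndarray) -> np.ndarray:
        """Per-element gradient (n_el, dim) of a nodal field."""
        return (self.gradient_operator() @ nodal).reshape(self.n_elements, self.dim)

    # ----------------------------------------------------------- integration
    def node_quadrature_weights(self) -> np.ndarray:
        """Nodal weights of the vertex quadrature: w_j = sum |T|/(d+1)."""
        if "nw" not in self._cache:
            m = self.n_elements
            w = np.repeat(self.element_volumes() / (self.dim + 1), self.dim + 1)
            nw = np.bincount(self.elements.ravel(), weights=w, minlength=self.n_nodes)
            self._cache["nw"] = nw
        return self._cache["nw"]

    def integrate(self, nodal: np.ndarray) -> float:
        """Exact integral of the P1 interpolant of a nodal field over Ω."""
        return float(self.node_quadrature_weights() @ nodal)

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    def tissue_volume(self, label: str) -> float:
        idx = self.tissue_names.index(label)
        return float(self.element_volumes()[self.element_tissue == idx].sum())

    def tissue_label_of(self, element_indices: np.ndarray | None = None) -> np.ndarray:
        """Array of string tissue labels per element."""
        names = np.asarray(self.tissue_names, dtype=object)
        t = self.element_tissue
        if element_indices is not None:
            t = t[element_indices]
        return names[t]

    # -------------------------------------------------------------- boundary
    def facet_measures(self) -> np.ndarray:
        """Length (2D) or area (3D) of every boundary facet."""
        if "fmeas" not in self._cache:
            x = self.nodes[self.boundary_facets]
            if self.dim == 2:
                meas = np.linalg.norm(x[:, 1] - x[:, 0], axis=1)
            else:
                c = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
                meas = 0.5 * np.linalg.norm(c, axis=1)
            self._cache["fmeas"] = meas
        return self._cache["fmeas"]

    def electrode_facets(self, ell: int) -> np.ndarray:
        """Indices (into boundary_facets) of facets owned by electrode ell."""
        return np.nonzero(self.facet_electrode == ell)[0]

    def electrode_areas(self) -> np.ndarray:
        """|e_ell| for ell = 1..L."""
        meas = self.facet_measures()
        return np.array(
            [meas[self.electrode_facets(ell)].sum() for ell in range(1, self.n_electrodes + 1)]
        )

    # -------------------------------------------------------- FEM matrices
    def mass_matrix(self) -> sp.csr_matrix:
        """P1 mass matrix M_ij = ∫ φ_i φ_j dx."""
        if "M" not in self._cache:
            d = self.dim
            nloc = d + 1
            vol = self.element_volumes()
            # local mass: |T|/((d+1)(d+2)) * (1 + delta_ij)
            loc = (np.ones((nloc, nloc)) + np.eye(nloc)) / ((d + 1) * (d + 2))
            vals = vol[:, None, None] * loc[None, :, :]
            rows = np.broadcast_to(self.elements[:, :, None], vals.shape)
            cols = np.broadcast_to(self.elements[:, None, :], vals.shape)
            M = sp.coo_matrix(
                (vals.ravel(), (rows.ravel(), cols.ravel())),
                shape=(self.n_nodes, self.n_nodes),
            )
            self._cache["M"] = M.tocsr()
        return self._cache["M"]

    def stiffness_matrix(self, sigma_nodal: np.ndarray) -> sp.csr_matrix:
        """Conductivity-weighted stiffness K_ij = ∫ σ ∇φ_i·∇φ_j dx.

        σ is the P1 interpolant of ``sigma_nodal``; its element average is
        exact for the integral since ∇φ is element-constant.
        """
        g = self.barycentric_gradients()  # (m, d+1, d)
        vol = self.element_volumes()
        sig_el = sigma_nodal[self.elements].mean(axis=1)
        loc = np.einsum("mid,mjd->mij", g, g) * (vol * sig_el)[:, None, None]
        rows = np.broadcast_to(self.elements[:, :, None], loc.shape)
        cols = np.broadcast_to(self.elements[:, None, :], loc.shape)
        K = sp.coo_matrix(
            (loc.ravel(), (rows.ravel(), cols.ravel())),
            shape=(self.n_nodes, self.n_nodes),
        )
        return K.tocsr()


# ---------------------------------------------------------------------------
def _locate(mesh: SimplexMesh, points: np.ndarray, n_candidates: int = 12):
    """Find containing element and barycentric coords for each point.

    Points outside the mesh are clamped to the nearest candidate element
    (barycentric coordinates clipped and renormalised).
    """
    cent = mesh.element_centroids()
    tree = cKDTree(cent)
    k = min(n_candidates, mesh.n_elements)
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    if cand.ndim == 1:
        cand = cand[:, None]
    g = mesh.barycentric_gradients()
    x0 = mesh.nodes[mesh.elements[:, 0]]
    n_pts = points.shape[0]
    elem_idx = np.empty(n_pts, dtype=int)
    bary = np.empty((n_pts, mesh.dim + 1))
    for i in range(n_pts):
        best_el, best_b, best_viol = -1, None, np.inf
        for e in cand[i]:
            # λ_j(x) = λ_j(x0) + ∇λ_j · (x - x0); λ(x0) = (1,0,..,0)
            lam = g[e] @ (points[i] - x0[e])
            lam[0] += 1.0
            viol = -lam.min()
            if viol < best_viol:
                best_viol, best_el, best_b = viol, e, lam
            if viol <= 1e-10:
                break
        lam = np.clip(best_b, 0.0, None)
        lam /= lam.sum()
        elem_idx[i] = best_el
        bary[i] = lam
    return elem_idx, bary


def p1_interpolation_matrix(src: SimplexMesh, dst_points: np.ndarray) -> sp.csr_matrix:
    """Sparse matrix P with (P v)_i = P1 interpolant of v at dst_points[i].

    Used to carry a conductivity defined on a coarse mesh onto the nodes of
    a finer potential mesh (two-mesh reconstruction protocol).
    """
    elem_idx, bary = _locate(src, np.asarray(dst_points, dtype=float))
    n_pts = dst_points.shape[0]
    nloc = src.dim + 1
    rows = np.repeat(np.arange(n_pts), nloc)
    cols = src.elements[elem_idx].ravel()
    P = sp.coo_matrix((bary.ravel(), (rows, cols)), shape=(n_pts, src.n_nodes))
    return P.tocsr()


# ---------------------------------------------------------------------------
def write_vtk(path, mesh: SimplexMesh, point_data: dict | None = None) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid.

    Tissue and electrode labels go out as cell data; ``point_data`` maps
    field names to nodal arrays.
    """
    nodes3 = np.zeros((mesh.n_nodes, 3))
    nodes3[:, : mesh.dim] = mesh.nodes
    nloc = mesh.dim + 1
    cell_type = 5 if mesh.dim == 2 else 10  # VTK_TRIANGLE / VTK_TETRA
    lines = [
        "# vtk DataFile Version 3.0",
        "eitmon mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in nodes3]
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * (nloc + 1)}")
    lines += [f"{nloc} " + " ".join(map(str, el)) for el in mesh.elements]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += [str(cell_type)] * mesh.n_elements
    lines.append(f"CELL_DATA {mesh.n_elements}")
    lines.append("SCALARS tissue int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(t)) for t in mesh.element_tissue]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{float(v):.9g}" for v in np.asarray(arr)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
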