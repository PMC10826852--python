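"""Parametric layered head phantoms for EIT hemorrhage-monitoring studies.

The phantom is a stack of concentric layers — scalp, skull, CSF and brain —
as a 2D disk (default, fast) or a 3D sphere, with surface electrodes and a
set of nested "hemorrhage" spheres/discs inside the brain whose conductivity
can be switched from brain tissue to blood to emulate a bleed growing over
time.  Tissue conductivities default to literature values at 1 kHz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .mesh import SimplexMesh

__all__ = [
    "TissueTable",
    "HeadPhantomSpec",
    "ReferenceImage",
    "build_phantom",
    "assign_conductivity",
    "make_reference",
    "sphere_volume_ml",
    "HEALTHY",
]

HEALTHY = "healthy"

# Conductivities (S/m) and relative permittivities at 1 kHz.  The
# permittivities are recorded for completeness only: the forward model is
# real-valued quasi-static conduction.
LITERATURE_CONDUCTIVITY = {
    "scalp": 0.32,
    "skull": 0.02,
    "csf": 2.00,
    "white_matter": 0.06,
    "gray_matter": 0.10,
    "cerebellum": 0.12,
    "blood": 0.70,
}
LITERATURE_PERMITTIVITY = {
    "scalp": 434_932.0,
    "skull": 2_702.0,
    "csf": 109.0,
    "white_matter": 69_810.0,
    "gray_matter": 164_062.0,
    "cerebellum": 164_358.0,
    "blood": 5_259.0,
}


def sphere_volume_ml(diameter_m: float) -> float:
    """Volume of a sphere with the given diameter, in millilitres."""
    return np.pi * diameter_m**3 / 6.0 * 1e6


def _hem_label(diameter_m: float, underlying: str) -> str:
    return f"hemorrhage:{diameter_m * 1e3:g}mm|{underlying}"


def parse_hemorrhage_label(label: str):
    """Return (diameter_m, underlying_tissue) or None for non-hemorrhage labels."""
    if not label.startswith("hemorrhage:"):
        return None
    body = label.split(":", 1)[1]
    diam, underlying = body.split("|")
    return float(diam[:-2]) * 1e-3, underlying


@dataclass
class TissueTable:
    """Tissue name → conductivity (S/m), with relative permittivity recorded."""

    conductivity: dict[str, float]
    permittivity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, val in self.conductivity.items():
            if val <= 0:
                raise ValueError(f"conductivity of {name!r} must be positive")
        required = {"scalp", "skull", "csf", "blood"}
        if not required <= set(self.conductivity):
            raise ValueError(f"tissue table must contain {sorted(required)}")
        has_brain = "brain" in self.conductivity or {
            "white_matter",
            "gray_matter",
        } <= set(self.conductivity)
        if not has_brain:
            raise ValueError("tissue table must contain 'brain' or white/gray matter")

    @classmethod
    def literature(cls, collapse_brain: str | None = None) -> "TissueTable":
        """Literature table at 1 kHz.

        With ``collapse_brain`` set to a tissue name (e.g. ``"white_matter"``),
        a single ``"brain"`` entry with that tissue's conductivity is added,
        for phantoms that treat the brain as one compartment.
        """
        cond = dict(LITERATURE_CONDUCTIVITY)
        perm = dict(LITERATURE_PERMITTIVITY)
        if collapse_brain is not None:
            cond["brain"] = cond[collapse_brain]
            perm["brain"] = perm[collapse_brain]
        return cls(cond, perm)

    def value(self, label: str, active_diameter: float | None = None) -> float:
        """Conductivity of a tissue or hemorrhage-shell label.

        A hemorrhage shell takes the blood value when its diameter is within
        the active hemorrhage (``active_diameter``), otherwise the value of
        the brain tissue it displaces.
        """
        hem = parse_hemorrhage_label(label)
        if hem is None:
            return self.conductivity[label]
        diam, underlying = hem
        if active_diameter is not None and diam <= active_diameter + 1e-12:
            return self.conductivity["blood"]
        return self.conductivity[underlying]


@dataclass
class HeadPhantomSpec:
    """Geometry of the layered head phantom.

    ``layer_radii`` are the outer radii (m) of scalp, skull, CSF and brain,
    strictly decreasing.  The hemorrhage is a set of nested spheres (discs in
    2D) of the given diameters around ``hemorrhage_center``; it must lie
    fully inside the brain layer.  ``location`` selects which brain tissue
    the bleed displaces: cortical bleeds grow into white matter, deep (basal
    ganglia) bleeds into gray matter.
    """

    dim: int = 2
    layer_radii: tuple[float, float, float, float] = (0.09, 0.085, 0.078, 0.076)
    n_electrodes: int = 16
    electrode_width: float = 0.01
    hemorrhage_center: tuple[float, ...] | None = None
    hemorrhage_diameters: tuple[float, ...] = (0.010, 0.015, 0.020, 0.025, 0.030)
    location: str = "cortical"
    distinct_brain: bool = False  # keep a gray-matter cortex shell distinct
    h: float = 0.008  # target element size (m)

    def __post_init__(self):
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        r = np.asarray(self.layer_radii)
        if not np.all(np.diff(r) < 0):
            raise ValueError("layer radii must be strictly decreasing inward")
        d = np.asarray(self.hemorrhage_diameters)
        if d.size and not np.all(np.diff(d) > 0):
            raise ValueError("hemorrhage diameters must be sorted ascending")
        if self.location not in ("cortical", "deep"):
            raise ValueError("location must be 'cortical' or 'deep'")
        if self.hemorrhage_center is None:
            r_brain = self.layer_radii[3]
            off = 0.62 * r_brain if self.location == "cortical" else 0.12 * r_brain
            self.hemorrhage_center = (0.0, off) if self.dim == 2 else (0.0, 0.0, off)
        if len(self.hemorrhage_center) != self.dim:
            raise ValueError("hemorrhage center dimension mismatch")
        if d.size:
            c = np.linalg.norm(self.hemorrhage_center)
            if c + d[-1] / 2 >= self.layer_radii[3]:
                raise ValueError(
                    "infeasible geometry: hemorrhage intersects the CSF/skull layers "
                    f"(|center| + Dmax/2 = {c + d[-1] / 2:.4f} m ≥ brain radius "
                    f"{self.layer_radii[3]:.4f} m)"
                )
        spacing = 2 * np.pi * self.layer_radii[0] / self.n_electrodes
        if not 0 < self.electrode_width < spacing:
            raise ValueError("electrode width must be in (0, inter-electrode spacing)")

    @property
    def brain_tissue(self) -> str:
        return "white_matter" if self.location == "cortical" else "gray_matter"


# --------------------------------------------------------------------- build
def _ring_radii(interfaces: np.ndarray, h: float) -> list[float]:
    """Interface radii plus evenly graded intermediate radii (spacing ≈ h)."""
    radii = []
    bounds = np.concatenate([[0.0], np.sort(interfaces)])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        gap = hi - lo
        n_mid = max(0, int(round(gap / h)) - 1)
        for k in range(1, n_mid + 1):
            radii.append(lo + gap * k / (n_mid + 1))
        radii.append(hi)
    return radii


def _circle_ring(r: float, n: int, phase: float) -> np.ndarray:
    """n points on a circle, radius inflated so the polygon area equals πr²."""
    r_eff = r * np.sqrt(2 * np.pi / n / np.sin(2 * np.pi / n))
    th = 2 * np.pi * np.arange(n) / n + phase
    return np.column_stack([r_eff * np.cos(th), r_eff * np.sin(th)])


def _build_points_2d(spec: HeadPhantomSpec):
    h = spec.h
    interfaces = np.asarray(spec.layer_radii)[::-1]
    pts = [np.zeros((1, 2))]
    h_bound = min(h, spec.electrode_width / 2.5)
    r_out = spec.layer_radii[0]
    for i, r in enumerate(_ring_radii(interfaces, h)):
        hr = h_bound if abs(r - r_out) < 1e-12 else h
        n = max(12, int(round(2 * np.pi * r / hr)))
        pts.append(_circle_ring(r, n, (i % 2) * np.pi / n))
    main = np.vstack(pts)

    diams = np.asarray(spec.hemorrhage_diameters)
    if diams.size == 0:
        return main
    c = np.asarray(spec.hemorrhage_center)
    h_hem = min(h, diams[0] / 3.0)
    hem = [c[None, :]]
    for i, r in enumerate(_ring_radii(diams / 2.0, h_hem)):
        n = max(16, int(round(2 * np.pi * r / h_hem)))
        hem.append(c + _circle_ring(r, n, (i % 2) * np.pi / n))
    hem = np.vstack(hem)
    keep = np.linalg.norm(main - c, axis=1) > diams[-1] / 2 + 0.6 * h_hem
    return np.vstack([main[keep], hem])


def _fibonacci_sphere(n: int, r: float, phase: float = 0.0) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere of radius r.

    The radius is inflated so that the convex hull of the points has the
    volume of the sphere (chord-deficit compensation).
    """
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    th = golden * i + phase
    pts = np.column_stack([rho * np.cos(th), rho * np.sin(th), z])
    from scipy.spatial import ConvexHull

    hull_vol = ConvexHull(pts).volume
    r_eff = r * (4.0 * np.pi / 3.0 / hull_vol) ** (1.0 / 3.0)
    return r_eff * pts


def _build_points_3d(spec: HeadPhantomSpec):
    h = spec.h
    interfaces = np.asarray(spec.layer_radii)[::-1]
    pts = [np.zeros((1, 3))]
    h_bound = min(h, spec.electrode_width / 2.0)
    r_out = spec.layer_radii[0]
    for i, r in enumerate(_ring_radii(interfaces, h)):
        hr = h_bound if abs(r - r_out) < 1e-12 else h
        n = max(14, int(round(4 * np.pi * r**2 / hr**2)))
        pts.append(_fibonacci_sphere(n, r, phase=0.73 * i))
    main = np.vstack(pts)

    diams = np.asarray(spec.hemorrhage_diameters)
    if diams.size == 0:
        return main
    c = np.asarray(spec.hemorrhage_center)
    h_hem = min(h, diams[0] / 2.5)
    hem = [c[None, :]]
    for i, r in enumerate(_ring_radii(diams / 2.0, h_hem)):
        n = max(10, int(round(4 * np.pi * r**2 / h_hem**2)))
        hem.append(c + _fibonacci_sphere(n, r, phase=0.41 * i))
    hem = np.vstack(hem)
    keep = np.linalg.norm(main - c, axis=1) > diams[-1] / 2 + 0.6 * h_hem
    return np.vstack([main[keep], hem])


def _electrode_centers_3d(L: int, r: float) -> np.ndarray:
    """Vertex plus three latitude rings on the upper half of the sphere.

    Approximates an EEG-cap style layout: one electrode at the vertex and
    the rest on rings whose populations scale with the ring circumference.
    """
    polar = np.array([np.pi / 6, np.pi / 3, 0.48 * np.pi])
    weights = np.sin(polar)
    counts = np.maximum(1, np.round((L - 1) * weights / weights.sum()).astype(int))
    while counts.sum() > L - 1:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < L - 1:
        counts[np.argmin(counts)] += 1
    centers = [np.array([0.0, 0.0, r])]
    for k, (theta, n) in enumerate(zip(polar, counts)):
        phi = 2 * np.pi * np.arange(n) / n + k * np.pi / max(n, 1)
        centers.append(
            np.column_stack(
                [
                    r * np.sin(theta) * np.cos(phi),
                    r * np.sin(theta) * np.sin(phi),
                    np.full(n, r * np.cos(theta)),
                ]
            )
        )
    return np.vstack(centers)


def _label_elements(spec: HeadPhantomSpec, centroids: np.ndarray, tissue_names: list[str]):
    r_scalp, r_skull, r_csf, r_brain = spec.layer_radii
    rr = np.linalg.norm(centroids, axis=1)
    labels = np.empty(len(centroids), dtype=int)

    def idx(name):
        return tissue_names.index(name)

    gray_shell = 0.85 * r_brain
    for i, r in enumerate(rr):
        if r <= r_brain:
            if spec.distinct_brain:
                labels[i] = idx("gray_matter") if r > gray_shell else idx("white_matter")
            else:
                labels[i] = idx("brain")
        elif r <= r_csf:
            labels[i] = idx("csf")
        elif r <= r_skull:
            labels[i] = idx("skull")
        else:
            labels[i] = idx("scalp")

    diams = np.asarray(spec.hemorrhage_diameters)
    if diams.size:
        c = np.asarray(spec.hemorrhage_center)
        dist = np.linalg.norm(centroids - c, axis=1)
        prev = 0.0
        for D in diams:
            name = _hem_label(D, spec.brain_tissue)
            inside = (dist > prev / 2) & (dist <= D / 2)
            labels[inside] = idx(name)
            prev = D
    return labels


def build_phantom(spec: HeadPhantomSpec, density: float | None = None) -> SimplexMesh:
    """Mesh the layered head phantom described by ``spec``.

    ``density`` overrides ``spec.h`` (target element size in metres).
    Electrodes are placed equi-angularly on the outer circle in 2D, and as
    an EEG-cap style upper-hemisphere layout in 3D.
    """
    if density is not None:
        spec = HeadPhantomSpec(
            **{**spec.__dict__, "h": density},
        )
    points = _build_points_2d(spec) if spec.dim == 2 else _build_points_3d(spec)
    tri = Delaunay(points)
    elements = tri.simplices

    tissue_names = ["scalp", "skull", "csf"]
    tissue_names += ["white_matter", "gray_matter"] if spec.distinct_brain else ["brain"]
    tissue_names += [_hem_label(D, spec.brain_tissue) for D in spec.hemorrhage_diameters]

    # boundary facets: facets of simplices with no neighbour
    bf = []
    for e, nbrs in enumerate(tri.neighbors):
        for v, nb in enumerate(nbrs):
            if nb == -1:
                facet = np.delete(elements[e], v)
                bf.append(facet)
    boundary_facets = np.asarray(bf, dtype=int)

    mesh = SimplexMesh(
        nodes=points,
        elements=elements,
        boundary_facets=boundary_facets,
        element_tissue=np.zeros(len(elements), dtype=int),
        tissue_names=tissue_names,
        facet_electrode=np.zeros(len(boundary_facets), dtype=int),
    )
    # drop degenerate slivers (co-circular point sets can produce them)
    vol = mesh.element_volumes()
    good = vol > 1e-6 * np.median(vol)
    mesh.elements = elements[good]
    mesh._cache.clear()

    mesh.element_tissue = _label_elements(spec, mesh.element_centroids(), tissue_names)
    mesh.facet_electrode = _assign_electrodes(spec, mesh)
    mesh.validate()
    return mesh


def _assign_electrodes(spec: HeadPhantomSpec, mesh: SimplexMesh) -> np.ndarray:
    L = spec.n_electrodes
    r_out = spec.layer_radii[0]
    mids = mesh.nodes[mesh.boundary_facets].mean(axis=1)
    labels = np.zeros(len(mids), dtype=int)
    if spec.dim == 2:
        ang = np.arctan2(mids[:, 1], mids[:, 0])
        half = (spec.electrode_width / r_out) / 2.0
        for ell in range(L):
            target = 2 * np.pi * ell / L
            d = np.angle(np.exp(1j * (ang - target)))
            labels[np.abs(d) <= half] = ell + 1
    else:
        centers = _electrode_centers_3d(L, r_out)
        cap = np.arcsin(min(1.0, (spec.electrode_width / 2.0) / r_out))
        u = mids / np.linalg.norm(mids, axis=1, keepdims=True)
        v = centers / r_out
        ang = np.arccos(np.clip(u @ v.T, -1.0, 1.0))  # (n_facets, L)
        nearest = np.argmin(ang, axis=1)
        within = ang[np.arange(len(mids)), nearest] <= cap
        labels[within] = nearest[within] + 1
        for ell in range(L):
            if not np.any(labels == ell + 1):
                labels[np.argmin(ang[:, ell])] = ell + 1
    return labels


# ----------------------------------------------------------- conductivity
def assign_conductivity(
    mesh: SimplexMesh, table: TissueTable, state: str | float
) -> np.ndarray:
    """Nodal conductivity field for a hemorrhage state.

    ``state`` is :data:`HEALTHY` or a hemorrhage diameter (m) from the
    phantom's diameter set; shells of diameter ≤ state take the blood value.
    Element values are converted to nodes by volume-weighted averaging,
    which smears tissue interfaces over one element layer.
    """
    if state == HEALTHY:
        active = None
    else:
        active = float(state)
        diams = [
            parse_hemorrhage_label(n)[0]
            for n in mesh.tissue_names
            if n.startswith("hemorrhage:")
        ]
        if not any(abs(D - active) < 1e-9 for D in diams):
            raise ValueError(
                f"unknown hemorrhage state {state!r}; phantom diameters: {diams}"
            )
    el_val = np.array(
        [table.value(name, active) for name in mesh.tissue_names]
    )[mesh.element_tissue]
    vol = mesh.element_volumes()
    num = np.bincount(
        mesh.elements.ravel(),
        weights=np.repeat(vol * el_val, mesh.dim + 1),
        minlength=mesh.n_nodes,
    )
    den = np.bincount(
        mesh.elements.ravel(),
        weights=np.repeat(vol, mesh.dim + 1),
        minlength=mesh.n_nodes,
    )
    return num / den


# -------------------------------------------------------- reference image
@dataclass
class ReferenceImage:
    """Structural prior extracted from anatomy (stand-in for a patient CT).

    ``kappa`` is a piecewise tissue-indicator image (scalp 0, skull 1,
    everything inside the skull 2); only its level-set geometry matters.
    ``nu_hat`` is the per-element unit gradient direction (zero where the
    gradient vanishes), ``gamma`` the per-element edge indicator (γ₁ on
    edges, 1 elsewhere) and the ROI is the brain compartment.
    """

    mesh: SimplexMesh
    kappa: np.ndarray  # nodal
    nu_hat: np.ndarray  # (n_el, dim)
    gamma: np.ndarray  # (n_el,)
    gamma1: float
    roi_elements: np.ndarray  # bool (n_el,)
    roi_nodes: np.ndarray  # bool (n_nodes,)
    node_compartment: np.ndarray  # int (n_nodes,): 0 scalp, 1 skull, 2 brain

    def weighting_tensor(self) -> np.ndarray:
        """Per-element tensor B = I − (1 − γ) ν̂ ν̂ᵀ (symmetric, eigs in [γ₁,1])."""
        d = self.mesh.dim
        eye = np.eye(d)[None, :, :]
        outer = self.nu_hat[:, :, None] * self.nu_hat[:, None, :]
        return eye - (1.0 - self.gamma)[:, None, None] * outer


def make_reference(
    mesh: SimplexMesh,
    threshold_frac: float = 0.5,
    gamma1: float = 0.01,
) -> ReferenceImage:
    """Build the reference image κ, edge indicator γ and ROI from the mesh.

    γ = γ₁ on elements whose ‖∇κ‖ is at least ``threshold_frac`` times the
    maximum gradient norm, 1 elsewhere.  A constant κ (degenerate anatomy)
    yields γ ≡ 1 and ν̂ ≡ 0 with a warning.
    """
    if not 0 < gamma1 < 1:
        raise ValueError("gamma1 must be in (0, 1) and small")
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")

    compartment_of = {}
    for i, name in enumerate(mesh.tissue_names):
        if name == "scalp":
            compartment_of[i] = 0
        elif name == "skull":
            compartment_of[i] = 1
        else:
            compartment_of[i] = 2
    el_comp = np.array([compartment_of[t] for t in mesh.element_tissue])

    # nodal κ: innermost compartment among adjacent elements (deterministic)
    kappa = np.zeros(mesh.n_nodes)
    np.maximum.at(
        kappa,
        mesh.elements.ravel(),
        np.repeat(el_comp.astype(float), mesh.dim + 1),
    )

    g = mesh.element_gradients(kappa)
    norm = np.linalg.norm(g, axis=1)
    gmax = norm.max()
    nu_hat = np.zeros_like(g)
    gamma = np.ones(mesh.n_elements)
    # scale-aware zero test: a genuine compartment edge has |∇κ| ≳ Δκ/diam
    diam = np.linalg.norm(mesh.nodes.max(0) - mesh.nodes.min(0))
    if gmax * diam <= 1e-6 * max(1.0, np.abs(kappa).max()):
        warnings.warn("reference image is constant: edge indicator γ ≡ 1")
    else:
        nz = norm > 1e-12 * gmax
        nu_hat[nz] = g[nz] / norm[nz, None]
        gamma[norm >= threshold_frac * gmax] = gamma1

    brain_ids = [
        i
        for i, name in enumerate(mesh.tissue_names)
        if name in ("brain", "white_matter", "gray_matter", "cerebellum")
        or name.startswith("hemorrhage:")
    ]
    roi_el = np.isin(mesh.element_tissue, brain_ids)
    roi_nodes = np.zeros(mesh.n_nodes, dtype=bool)
    roi_nodes[np.unique(mesh.elements[roi_el])] = True

    return ReferenceImage(
        mesh=mesh,
        kappa=kappa,
        nu_hat=nu_hat,
        gamma=gamma,
        gamma1=gamma1,
        roi_elements=roi_el,
        roi_nodes=roi_nodes,
        node_compartment=kappa.astype(int),
    )
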