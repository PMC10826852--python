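"""Nonlinear ROI difference imaging (monitoring algorithm) tests."""

import numpy as np
import pytest
import scipy.linalg as sla
import scipy.sparse as sp

from eitmon.forward import simulate_frame
from eitmon.phantom import ReferenceImage, assign_conductivity
from eitmon.priors import TVFunctional, WeightedTVFunctional
from eitmon.recon_absolute import GNSettings
from eitmon.recon_monitoring import (
    MLSQRSettings,
    extension_map,
    mlsqr_solve,
    reconstruct_monitoring,
)

GN = GNSettings(sigma_min=1e-3)


@pytest.fixture(scope="module")
def mo_growth(study):
    return reconstruct_monitoring(
        study.frame(0.015, 0), study.frame(0.020, 1), study.op, study.ref, gn=GN
    )


class TestMLSQR:
    def make_problem(self, n_unknown=50, n_res=80, seed=0):
        rng = np.random.default_rng(seed)
        J = rng.normal(size=(n_res, n_unknown))
        A = rng.normal(size=(n_unknown, n_unknown))
        H = A @ A.T + n_unknown * np.eye(n_unknown)
        L = sla.cholesky(H, lower=True)
        r = rng.normal(size=n_res)
        g = rng.normal(size=n_unknown)
        return J, H, L, r, g

    def test_matches_dense_normal_equations(self):
        """Prior-conditioned LSQR equals the dense solve of
        (JᵀJ + H) d = Jᵀr − g on a 50-unknown problem (1e-6 relative)."""
        J, H, L, r, g = self.make_problem()
        dense = np.linalg.solve(J.T @ J + H, J.T @ r - g)
        d, flagged = mlsqr_solve(J, r, L, g, MLSQRSettings(max_iter=500, tol=1e-10))
        assert not flagged
        assert np.linalg.norm(d - dense) / np.linalg.norm(dense) < 1e-6

    def test_zero_rhs_gives_zero_direction(self):
        J, H, L, _, _ = self.make_problem(seed=1)
        d, _ = mlsqr_solve(J, np.zeros(J.shape[0]), L, np.zeros(J.shape[1]))
        assert np.allclose(d, 0.0)

    def test_identity_prior_damped_least_squares(self):
        """With FᵀF = I and square J the direction is the classical damped
        least-squares solution (JᵀJ + I)⁻¹Jᵀr."""
        rng = np.random.default_rng(2)
        n = 40
        J = np.eye(n) + 0.1 * rng.normal(size=(n, n))
        r = rng.normal(size=n)
        closed_form = np.linalg.solve(J.T @ J + np.eye(n), J.T @ r)
        d, _ = mlsqr_solve(
            J, r, np.eye(n), np.zeros(n), MLSQRSettings(max_iter=400, tol=1e-12)
        )
        assert np.linalg.norm(d - closed_form) / np.linalg.norm(closed_form) < 1e-8

    def test_iteration_limit_flagged(self):
        J, H, L, r, g = self.make_problem(seed=3)
        _, flagged = mlsqr_solve(J, r, L, g, MLSQRSettings(max_iter=2, tol=1e-14))
        assert flagged


class TestExtensionMap:
    def test_support_and_zero_extension(self):
        roi = np.array([False, True, False, True, False])
        K = extension_map(roi)
        x = np.array([1.5, -2.0])
        full = K @ x
        assert np.array_equal(full, [0.0, 1.5, 0.0, -2.0, 0.0])
        assert np.array_equal(K.T @ full, x)


class TestMonitoring:
    def test_delta_supported_on_roi(self, study, mo_growth):
        """δ̂σ vanishes identically outside the brain ROI (exact zeros)."""
        outside = ~study.ref.roi_nodes
        assert np.all(mo_growth.delta_sigma[outside] == 0.0)
        assert np.any(mo_growth.delta_sigma != 0.0)

    def test_objective_monotone_and_positive(self, study, mo_growth):
        trace = np.asarray(mo_growth.cost_trace)
        assert np.all(np.diff(trace) <= 0)
        assert np.all(mo_growth.sigma1 >= GN.sigma_min)
        assert np.all(mo_growth.sigma2 >= GN.sigma_min)

    def test_growth_localizes(self, study, mo_growth):
        from eitmon.detect import positive_com

        com = positive_com(mo_growth.delta_sigma, study.op.cond_mesh)
        ctr = np.asarray(study.spec.hemorrhage_center)
        assert np.linalg.norm(com - ctr) < 0.010

    def test_no_growth_much_smaller_than_growth(self, study):
        """Repeated measurements of the same state give a δ̂σ at least 5×
        smaller (L2) than a 20→30 mm growth on the same phantom."""
        grow = reconstruct_monitoring(
            study.frame(0.020, 0), study.frame(0.030, 1), study.op, study.ref, gn=GN
        )
        still = reconstruct_monitoring(
            study.frame(0.020, 0), study.frame(0.020, 1), study.op, study.ref, gn=GN
        )
        assert np.linalg.norm(still.delta_sigma) < np.linalg.norm(grow.delta_sigma) / 5

    def test_empty_roi_rejected(self, study):
        import copy

        ref = copy.copy(study.ref)
        ref.roi_nodes = np.zeros(study.op.cond_mesh.n_nodes, dtype=bool)
        with pytest.raises(ValueError, match="ROI"):
            reconstruct_monitoring(
                study.frame(0.015, 0), study.frame(0.020, 1), study.op, ref, gn=GN
            )

    def test_modeling_error_shielding(self, study):
        """A frame-invariant global conductivity bias (2%) perturbs the σ₁
        estimate more than the δσ estimate (L2, relative to field scale)."""
        f1, f2 = study.frame(0.015, 0), study.frame(0.020, 1)
        base = reconstruct_monitoring(f1, f2, study.op, study.ref, gn=GN)

        z, pat, obs = study.op.z, study.op.patterns, study.op.observation
        frames_b = []
        for state, role in [(0.015, 0), (0.020, 1)]:
            sig = 1.02 * assign_conductivity(study.sim_mesh, study.table, state)
            frames_b.append(
                simulate_frame(
                    study.sim_mesh,
                    sig,
                    z,
                    pat,
                    obs,
                    study.noise_std,
                    seed=study.frame(state, role).seed,
                )
            )
        biased = reconstruct_monitoring(
            frames_b[0], frames_b[1], study.op, study.ref, gn=GN
        )
        d_sigma1 = np.linalg.norm(biased.sigma1 - base.sigma1)
        d_delta = np.linalg.norm(biased.delta_sigma - base.delta_sigma)
        assert d_delta < d_sigma1

    def test_full_domain_reduction_matches_dense_oracle(self, table, setup16):
        """With Ω_ROI = Ω and γ ≡ 1 the algorithm is plain joint nonlinear
        difference imaging; its iterates match a brute-force Gauss–Newton
        with dense direct solves to 1e-5 relative.  The mesh is kept small
        enough that the inner LSQR converges to solver precision."""
        from eitmon.forward import ForwardOperator
        from eitmon.phantom import HeadPhantomSpec, build_phantom

        unit_mesh = build_phantom(
            HeadPhantomSpec(dim=2, h=0.016, hemorrhage_diameters=(0.020, 0.030))
        )
        unit_op = ForwardOperator(unit_mesh, setup16.z, setup16.patterns, setup16.obs)
        ref = ReferenceImage(
            mesh=unit_mesh,
            kappa=np.zeros(unit_mesh.n_nodes),
            nu_hat=np.zeros((unit_mesh.n_elements, unit_mesh.dim)),
            gamma=np.ones(unit_mesh.n_elements),
            gamma1=0.01,
            roi_elements=np.ones(unit_mesh.n_elements, dtype=bool),
            roi_nodes=np.ones(unit_mesh.n_nodes, dtype=bool),
            node_compartment=np.zeros(unit_mesh.n_nodes, dtype=int),
        )
        f1 = simulate_frame(
            unit_mesh,
            assign_conductivity(unit_mesh, table, 0.020),
            setup16.z,
            setup16.patterns,
            setup16.obs,
            1e-6,
            seed=31,
        )
        f2 = simulate_frame(
            unit_mesh,
            assign_conductivity(unit_mesh, table, 0.030),
            setup16.z,
            setup16.patterns,
            setup16.obs,
            1e-6,
            seed=32,
        )
        tv_d = TVFunctional(unit_mesh, alpha=0.005, beta=0.001)
        wtv = WeightedTVFunctional(unit_mesh, ref, alpha=0.01, beta=0.001)
        gn1 = GNSettings(sigma_min=1e-3, max_iter=1)
        res = reconstruct_monitoring(
            f1, f2, unit_op, ref, tv_d, wtv, gn1,
            MLSQRSettings(max_iter=2000, tol=1e-13),
        )

        # independent brute-force GN: dense normal-equations solves
        from eitmon.forward import fit_three_compartment

        n = unit_mesh.n_nodes
        sigma1 = fit_three_compartment(f1, unit_op, ref, bounds=(0.01, 3.0))
        r_init = f1.V - unit_op.measure(sigma1)
        w = 1.0 / max(f1.noise_std, float(np.sqrt(np.mean(r_init**2))))
        dsig = np.zeros(n)

        def objective(s1, ds):
            r1 = f1.V - unit_op.measure(s1)
            r2 = f2.V - unit_op.measure(s1 + ds)
            rho = np.concatenate([w * r1, w * r2])
            return (
                float(rho @ rho)
                + wtv.eval_grad_hess(s1)[0]
                + tv_d.eval_grad_hess(ds)[0],
                rho,
            )

        cost, rho = objective(sigma1, dsig)
        prev = 1.0
        for _ in range(gn1.max_iter):
            J1 = unit_op.jacobian(sigma1)
            J2 = unit_op.jacobian(sigma1 + dsig)
            Jt = np.sqrt(2) * np.block([[w * J1, np.zeros((J1.shape[0], n))], [w * J2, w * J2]])
            g = np.concatenate(
                [wtv.eval_grad_hess(sigma1)[1], tv_d.eval_grad_hess(dsig)[1]]
            )
            H = sp.block_diag(
                [
                    wtv.regularized_hessian(sigma1, 1e-8),
                    tv_d.regularized_hessian(dsig, 1e-8),
                ]
            ).toarray()
            d = np.linalg.solve(Jt.T @ Jt + H, Jt.T @ (np.sqrt(2) * rho) - g)
            act1 = (sigma1 <= gn1.sigma_min * 1.001) & (d[:n] < 0)
            d[:n][act1] = 0.0
            s2 = sigma1 + dsig
            act2 = (s2 <= gn1.sigma_min * 1.001) & (d[n:] < 0)
            d[n:][act2] = 0.0
            step = min(1.0, prev / gn1.ls_backtrack**2)
            for _t in range(gn1.ls_max_trials):
                s1n = np.maximum(sigma1 + step * d[:n], gn1.sigma_min)
                dsn = np.maximum(dsig + step * d[n:], gn1.sigma_min - s1n)
                cn, rn = objective(s1n, dsn)
                if cn < cost:
                    break
                step *= gn1.ls_backtrack
            else:
                break
            prev = step
            rel = (cost - cn) / cost
            sigma1, dsig, cost, rho = s1n, dsn, cn, rn
            if rel < gn1.cost_tol:
                break

        scale = np.abs(res.sigma1).max()
        assert np.abs(res.sigma1 - sigma1).max() < 1e-5 * scale
        dscale = max(np.abs(dsig).max(), 1e-12)
        assert np.abs(res.delta_sigma - dsig).max() < 1e-4 * dscale
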