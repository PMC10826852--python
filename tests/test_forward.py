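"""Complete-electrode-model forward solver and fitting tests."""

import numpy as np
import pytest

from eitmon.forward import (
    ContactImpedances,
    CurrentPatternSet,
    MeasurementFrame,
    ObservationOperator,
    fit_constant_sigma,
    fit_three_compartment,
    forward,
    jacobian,
    simulate_frame,
)
from eitmon.phantom import (
    HEALTHY,
    HeadPhantomSpec,
    assign_conductivity,
    build_phantom,
)


class TestPatterns:
    def test_skip_default_matches_cap_offset(self):
        p32 = CurrentPatternSet.pairwise_skip(32)
        assert p32.descriptor == "pairwise skip-12"
        # electrode 1 sources, electrode 13 sinks (0-based 0 and 12)
        assert p32.matrix[0, 0] > 0 and p32.matrix[0, 12] < 0

    def test_row_sum_violation_rejected(self):
        bad = np.zeros((1, 16))
        bad[0, 0] = 1e-3
        with pytest.raises(ValueError, match="sum to zero"):
            CurrentPatternSet(bad)

    def test_duplicates_rejected(self):
        row = np.zeros(16)
        row[0], row[5] = 1e-3, -1e-3
        with pytest.raises(ValueError, match="duplicate"):
            CurrentPatternSet(np.vstack([row, row]))

    def test_observation_kills_constants(self, setup16):
        U = np.ones((setup16.patterns.n_patterns, 16)) * 3.7
        assert np.allclose(setup16.obs.apply(U, setup16.patterns), 0.0)

    def test_drop_injecting_mask(self, setup16):
        obs = ObservationOperator(16, drop_injecting=True)
        mask = obs.channel_mask(setup16.patterns)
        # each injection activates 2 electrodes, each touching 2 channels
        assert mask.shape == (16, 16)
        assert np.all(mask.sum(axis=1) == 12)


class TestForwardSolve:
    def test_ground_condition(self, unit_mesh, table, setup16):
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        sol = forward(unit_mesh, sigma, setup16.z, setup16.patterns)
        scale = np.abs(sol.U).max()
        assert np.abs(sol.U.sum(axis=1)).max() < 1e-12 * max(scale, 1.0)

    def test_current_conservation(self, unit_mesh, table, setup16):
        """Electrode currents recovered from the discrete solution match the
        injected pattern (1e-10 relative)."""
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        sol = forward(unit_mesh, sigma, setup16.z, setup16.patterns)
        meas = unit_mesh.facet_measures()
        L = 16
        for k in range(setup16.patterns.n_patterns):
            I_rec = np.zeros(L)
            for ell in range(1, L + 1):
                zl = setup16.z.values[ell - 1]
                for f in unit_mesh.electrode_facets(ell):
                    nodes = unit_mesh.boundary_facets[f]
                    u_avg = sol.u[nodes, k].mean()
                    I_rec[ell - 1] += meas[f] / zl * (sol.U[k, ell - 1] - u_avg)
            ref = np.abs(setup16.patterns.matrix[k]).max()
            assert np.abs(I_rec.sum()) < 1e-10 * ref
            assert np.abs(I_rec - setup16.patterns.matrix[k]).max() < 1e-8 * ref

    def test_conductivity_scaling(self, unit_mesh, table, setup16):
        """(σ, z) → (2σ, z/2) halves every voltage exactly."""
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        sol = forward(unit_mesh, sigma, setup16.z, setup16.patterns)
        half_z = ContactImpedances(setup16.z.values / 2)
        sol2 = forward(unit_mesh, 2 * sigma, half_z, setup16.patterns)
        assert np.allclose(sol2.U, sol.U / 2, rtol=1e-10)

    def test_reciprocity(self, unit_mesh, table, setup16):
        """Swap injection and measurement pairs: voltages agree to 1e-8."""
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        L = 16
        for (a, b), (c, d) in [((0, 5), (8, 12)), ((1, 9), (3, 14))]:
            I = np.zeros((2, L))
            I[0, a], I[0, b] = 1e-3, -1e-3
            I[1, c], I[1, d] = 1e-3, -1e-3
            sol = forward(unit_mesh, sigma, setup16.z, CurrentPatternSet(I))
            m1 = sol.U[0, c] - sol.U[0, d]
            m2 = sol.U[1, a] - sol.U[1, b]
            assert abs(m1 - m2) <= 1e-8 * abs(m1)

    def test_mirror_symmetry(self, setup16):
        """Homogeneous disk, injection through a mirror-symmetric pair:
        voltages are symmetric under the reflection within mesh error."""
        spec = HeadPhantomSpec(dim=2, h=0.012, hemorrhage_diameters=())
        mesh = build_phantom(spec)
        sigma = np.full(mesh.n_nodes, 0.3)
        L = 16
        I = np.zeros((1, L))
        I[0, 0], I[0, 8] = 1e-3, -1e-3  # opposite pair on the x-axis
        sol = forward(mesh, sigma, setup16.z, CurrentPatternSet(I))
        U = sol.U[0]
        # reflection about the x-axis maps electrode ℓ to L-ℓ
        mirrored = np.concatenate([[U[0]], U[1:][::-1]])
        assert np.abs(U - mirrored).max() < 0.02 * np.abs(U).max()

    def test_no_electrodes_rejected(self, unit_mesh, table, setup16):
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        bare = type(unit_mesh)(
            nodes=unit_mesh.nodes,
            elements=unit_mesh.elements,
            boundary_facets=unit_mesh.boundary_facets,
            element_tissue=unit_mesh.element_tissue,
            tissue_names=unit_mesh.tissue_names,
            facet_electrode=np.zeros(len(unit_mesh.boundary_facets), dtype=int),
        )
        from eitmon.forward import assemble_cem

        with pytest.raises(ValueError, match="singular|no electrodes"):
            assemble_cem(bare, sigma, setup16.z)


class TestJacobian:
    def test_against_finite_differences(self, unit_mesh, table, setup16):
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        J = jacobian(unit_mesh, sigma, setup16.z, setup16.patterns, setup16.obs)
        rng = np.random.default_rng(3)
        eps = 1e-6
        scale = np.abs(J).max()
        for j in rng.choice(unit_mesh.n_nodes, 6, replace=False):
            sp = sigma.copy()
            sp[j] += eps
            sm = sigma.copy()
            sm[j] -= eps
            up = forward(unit_mesh, sp, setup16.z, setup16.patterns).U
            um = forward(unit_mesh, sm, setup16.z, setup16.patterns).U
            fd = (
                setup16.obs.apply(up, setup16.patterns)
                - setup16.obs.apply(um, setup16.patterns)
            ) / (2 * eps)
            assert np.abs(J[:, j] - fd).max() < 1e-4 * scale

    def test_sensitivity_decays_with_depth(self, unit_mesh, table, setup16):
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        J = jacobian(unit_mesh, sigma, setup16.z, setup16.patterns, setup16.obs)
        r = np.linalg.norm(unit_mesh.nodes, axis=1)
        col = np.linalg.norm(J, axis=0)
        deep = col[r < 0.03].mean()
        shallow = col[r > 0.08].mean()
        assert deep < shallow

    def test_first_order_taylor(self, unit_mesh, table, setup16):
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        J = jacobian(unit_mesh, sigma, setup16.z, setup16.patterns, setup16.obs)
        v0 = setup16.obs.apply(
            forward(unit_mesh, sigma, setup16.z, setup16.patterns).U, setup16.patterns
        )
        errs = []
        for eps in (1e-3, 5e-4):
            v1 = setup16.obs.apply(
                forward(unit_mesh, sigma * (1 + eps), setup16.z, setup16.patterns).U,
                setup16.patterns,
            )
            errs.append(np.linalg.norm(v1 - v0 - eps * (J @ sigma)))
        # quadratic remainder: halving eps shrinks the error ~4x
        assert errs[1] < 0.35 * errs[0]

    def test_dimension_mismatch(self, unit_mesh, table, setup16):
        with pytest.raises(ValueError, match="length"):
            jacobian(unit_mesh, np.ones(3), setup16.z, setup16.patterns, setup16.obs)


class TestSimulation:
    def test_zero_noise_exact(self, unit_mesh, table, setup16):
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        fr = simulate_frame(unit_mesh, sigma, setup16.z, setup16.patterns, setup16.obs)
        assert np.array_equal(fr.V, fr.noise_free)
        assert fr.noise_std == 0.0

    def test_relative_noise_convention(self, unit_mesh, table, setup16):
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        fr = simulate_frame(
            unit_mesh,
            sigma,
            setup16.z,
            setup16.patterns,
            setup16.obs,
            noise_std=6.7e-4,
            seed=0,
            relative_noise=True,
        )
        assert fr.noise_std == pytest.approx(6.7e-4 * np.abs(fr.noise_free).max())

    def test_seed_reproducibility(self, unit_mesh, table, setup16):
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        a = simulate_frame(
            unit_mesh, sigma, setup16.z, setup16.patterns, setup16.obs, 1e-5, seed=42
        )
        b = simulate_frame(
            unit_mesh, sigma, setup16.z, setup16.patterns, setup16.obs, 1e-5, seed=42
        )
        assert np.array_equal(a.V, b.V)
        assert not np.array_equal(a.V, a.noise_free)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            MeasurementFrame(V=np.zeros(4), noise_std=-1.0)


class TestFitting:
    def test_constant_fit_recovers_truth(self, unit_mesh, setup16, unit_op):
        sigma = np.full(unit_mesh.n_nodes, 0.2)
        fr = simulate_frame(unit_mesh, sigma, setup16.z, setup16.patterns, setup16.obs)
        fit = fit_constant_sigma(fr, unit_op)
        assert fit[0] == pytest.approx(0.2, rel=0.01)

    def test_constant_fit_is_minimum(self, unit_mesh, table, setup16, unit_op):
        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        fr = simulate_frame(unit_mesh, sigma, setup16.z, setup16.patterns, setup16.obs)
        fit = fit_constant_sigma(fr, unit_op)
        c = fit[0]

        def cost(cc):
            return np.sum((fr.V - unit_op.measure(np.full(unit_mesh.n_nodes, cc))) ** 2)

        assert cost(c / 10) > cost(c) and cost(10 * c) > cost(c)
        # effective medium: between the least and most conductive tissue
        assert min(table.conductivity.values()) < c < max(table.conductivity.values())

    def test_three_compartment_recovery(self, unit_mesh, setup16, unit_op, unit_ref):
        """Noise-free data from a genuinely three-compartment phantom is
        inverted to all three values within 5%."""
        truth = np.array([0.32, 0.04, 0.25])
        sigma = truth[unit_ref.node_compartment]
        fr = simulate_frame(unit_mesh, sigma, setup16.z, setup16.patterns, setup16.obs)
        fit = fit_three_compartment(fr, unit_op, unit_ref)
        for c in range(3):
            got = fit[unit_ref.node_compartment == c][0]
            assert got == pytest.approx(truth[c], rel=0.05)

    def test_skull_fitted_below_scalp(self, unit_mesh, setup16, unit_op, unit_ref):
        truth = np.array([0.32, 0.02, 0.25])
        sigma = truth[unit_ref.node_compartment]
        fr = simulate_frame(unit_mesh, sigma, setup16.z, setup16.patterns, setup16.obs)
        fit = fit_three_compartment(fr, unit_op, unit_ref)
        scalp = fit[unit_ref.node_compartment == 0][0]
        skull = fit[unit_ref.node_compartment == 1][0]
        assert skull < 0.5 * scalp

    def test_collapsed_compartments_match_constant_fit(
        self, unit_mesh, table, setup16, unit_op, unit_ref
    ):
        import copy

        sigma = assign_conductivity(unit_mesh, table, HEALTHY)
        fr = simulate_frame(unit_mesh, sigma, setup16.z, setup16.patterns, setup16.obs)
        flat_ref = copy.copy(unit_ref)
        flat_ref.node_compartment = np.zeros(unit_mesh.n_nodes, dtype=int)
        a = fit_three_compartment(fr, unit_op, flat_ref)
        b = fit_constant_sigma(fr, unit_op)
        assert a[0] == pytest.approx(b[0], rel=1e-3)

    def test_empty_frame_rejected(self, unit_op):
        with pytest.raises(ValueError, match="empty"):
            fit_constant_sigma(MeasurementFrame(V=np.array([]), noise_std=0.0), unit_op)
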