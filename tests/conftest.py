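"""Shared fixtures: small phantoms, electrode setups and simulated frames.

Everything is generated at test time; meshes are kept small so the whole
suite runs on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from eitmon.forward import (
    ContactImpedances,
    CurrentPatternSet,
    ForwardOperator,
    ObservationOperator,
    simulate_frame,
)
from eitmon.phantom import (
    HEALTHY,
    HeadPhantomSpec,
    TissueTable,
    assign_conductivity,
    build_phantom,
    make_reference,
)


@pytest.fixture(scope="session")
def unit_spec():
    return HeadPhantomSpec(dim=2, h=0.012, hemorrhage_diameters=(0.015, 0.020, 0.030))


@pytest.fixture(scope="session")
def unit_mesh(unit_spec):
    return build_phantom(unit_spec)


@pytest.fixture(scope="session")
def table(unit_spec):
    return TissueTable.literature(collapse_brain=unit_spec.brain_tissue)


@dataclass
class ElectrodeSetup:
    z: ContactImpedances
    patterns: CurrentPatternSet
    obs: ObservationOperator


@pytest.fixture(scope="session")
def setup16():
    L = 16
    return ElectrodeSetup(
        z=ContactImpedances.uniform(L),
        patterns=CurrentPatternSet.pairwise_skip(L),
        obs=ObservationOperator(L),
    )


@pytest.fixture(scope="session")
def unit_op(unit_mesh, setup16):
    """Single-mesh forward operator on the coarse unit phantom."""
    return ForwardOperator(unit_mesh, setup16.z, setup16.patterns, setup16.obs)


@pytest.fixture(scope="session")
def unit_ref(unit_mesh):
    return make_reference(unit_mesh)


@dataclass
class TwoMeshStudy:
    """Fine simulation mesh plus coarser reconstruction meshes and frames."""

    spec: HeadPhantomSpec
    table: TissueTable
    sim_mesh: object
    op: ForwardOperator
    ref: object
    noise_std: float
    frames: dict  # (state, role) -> MeasurementFrame

    def frame(self, state, role=0):
        return self.frames[(state, role)]


@pytest.fixture(scope="session")
def study(setup16):
    """Two-mesh monitoring study: cortical inclusion chain at device noise."""
    spec = HeadPhantomSpec(dim=2, h=0.009, hemorrhage_diameters=(0.015, 0.020, 0.030))
    table = TissueTable.literature(collapse_brain=spec.brain_tissue)
    sim = build_phantom(spec, density=0.004)
    pot = build_phantom(spec, density=0.0065)
    cond = build_phantom(spec, density=0.009)
    op = ForwardOperator(pot, setup16.z, setup16.patterns, setup16.obs, cond_mesh=cond)
    ref = make_reference(cond)
    healthy = assign_conductivity(sim, table, HEALTHY)
    v0 = simulate_frame(sim, healthy, setup16.z, setup16.patterns, setup16.obs).V
    std = 6.7e-4 * np.abs(v0).max()
    frames = {}
    for i, state in enumerate([HEALTHY, 0.015, 0.020, 0.030]):
        sig = assign_conductivity(sim, table, state)
        for role in (0, 1):
            frames[(state, role)] = simulate_frame(
                sim,
                sig,
                setup16.z,
                setup16.patterns,
                setup16.obs,
                std,
                seed=1000 + 10 * i + role,
                label=f"t{role + 1}",
            )
    return TwoMeshStudy(
        spec=spec,
        table=table,
        sim_mesh=sim,
        op=op,
        ref=ref,
        noise_std=std,
        frames=frames,
    )
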