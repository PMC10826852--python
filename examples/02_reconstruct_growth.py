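"""Reconstruct a hemorrhage growth step with all three algorithms.

Simulates two acquisitions of the cortical phantom (15 mm and 20 mm bleed,
a 2.42 ml volume increase on the equivalent-sphere scale) at device noise,
then reconstructs the conductivity change with

* TV  — TV-regularized absolute imaging of each frame, change by subtraction,
* LD  — one-step linear difference imaging with a Gaussian smoothness prior,
* MO  — nonlinear ROI difference imaging with parallel-level-sets prior.

Prints the integral of each estimate and how far its positive blob sits
from the true hemorrhage centre.
"""

import warnings

import numpy as np

from eitmon.detect import positive_com
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
from eitmon.priors import TVFunctional, build_smoothness_prior
from eitmon.recon_absolute import GNSettings, difference_by_subtraction, reconstruct_absolute
from eitmon.recon_linear import linearize, reconstruct_linear
from eitmon.recon_monitoring import reconstruct_monitoring

warnings.filterwarnings("ignore")

spec = HeadPhantomSpec(dim=2, n_electrodes=16)
table = TissueTable.literature(collapse_brain=spec.brain_tissue)
sim = build_phantom(spec, density=0.004)     # data simulation (fine)
pot = build_phantom(spec, density=0.0065)    # potential mesh (inversion)
cond = build_phantom(spec, density=0.009)    # conductivity mesh (inversion)

z = ContactImpedances.uniform(16)
patterns = CurrentPatternSet.pairwise_skip(16)
obs = ObservationOperator(16)
op = ForwardOperator(pot, z, patterns, obs, cond_mesh=cond)
ref = make_reference(cond)

healthy = assign_conductivity(sim, table, HEALTHY)
std = 6.7e-4 * np.abs(simulate_frame(sim, healthy, z, patterns, obs).V).max()
f1 = simulate_frame(sim, assign_conductivity(sim, table, 0.015), z, patterns, obs,
                    std, seed=1, label="t1")
f2 = simulate_frame(sim, assign_conductivity(sim, table, 0.020), z, patterns, obs,
                    std, seed=2, label="t2")

ctr = np.asarray(spec.hemorrhage_center)
gn = GNSettings(sigma_min=1e-3)


def report(name, dsigma):
    integral = cond.integrate(dsigma)
    dist = np.linalg.norm(positive_com(dsigma, cond) - ctr)
    print(f"{name}: integral {integral:+.3e} S/m*m^2, "
          f"positive blob {dist * 1e3:.1f} mm from the true centre")


tv = TVFunctional(cond, alpha=0.01, beta=0.001)
r1 = reconstruct_absolute(f1, op, tv, gn)
r2 = reconstruct_absolute(f2, op, tv, gn)
report("TV (absolute + subtraction)", difference_by_subtraction(r1, r2))

model = linearize(f1, op)
l_omega = pot.nodes[:, 0].max() - pot.nodes[:, 0].min()
prior = build_smoothness_prior(cond, 2 * model.sigma0[0], l_omega / 4, 0.01)
report("LD (linear difference)     ", reconstruct_linear(f1, f2, model, prior).delta_sigma)

mo = reconstruct_monitoring(f1, f2, op, ref, gn=gn)
report("MO (nonlinear ROI diff.)   ", mo.delta_sigma)
print("\nPositive integrals flag the growing bleed; the monitoring algorithm's"
      "\nestimate is confined to the brain ROI and localizes the growth best.")
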