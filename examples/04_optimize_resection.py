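"""Search for optimal virtual resections with simulated annealing.

Generates one synthetic patient, sweeps resection sizes, and reports the
optimal resection (smallest with a 90% drop in simulated propagation) and
the disconnecting resection (smallest that isolates the seed).
"""

import time

import numpy as np

from esses import CohortSpec, SAConfig, SIRParameters, generate_patient, resection_size_sweep
from esses.resection import Resection, delta_ir, overlap_with_plan

spec = CohortSpec(n_roi=40, ez_size=5, rng_seed=3)
patient = generate_patient(spec, "SF", rng=3)
params = SIRParameters(gamma=spec.generating_gamma, n_realizations=120, rng_seed=3)

t0 = time.time()
sweep = resection_size_sweep(
    patient.network, patient.seed_map, sizes=range(1, 13),
    sir_params=params,
    sa_config=SAConfig(n_restarts=3, proposals_per_temp=30),
    rng_seed=3,
)
print(f"size sweep in {time.time() - t0:.0f}s; baseline IR0 = {sweep.ir0[0]:.3f}")
for size, d, e in zip(sweep.sizes, sweep.delta_ir_mean, sweep.seed_eff_norm):
    print(f"  S = {size:2d}: delta-IR = {d:.3f}, e_R = {e:.3f}")
print(f"optimal resection:      S(R_op) = {sweep.s_rop} (censored: {sweep.censored})")
print(f"disconnecting resection: S(R_D) = {sweep.r_d.size if sweep.r_d else None}")

# simulate the planned resection and compare with the optimized one
d_ra, sd_ra = delta_ir(patient.network, Resection(patient.resection_area), patient.seed_map, params)
reference = sweep.r_op if sweep.r_op is not None else sweep.resections[-1]
print(f"planned resection: size {len(patient.resection_area)}, "
      f"delta-IR = {d_ra:.3f} +- {sd_ra:.3f}, "
      f"overlap with R_op = {overlap_with_plan(reference, patient.resection_area):.2f}")
# delta-IR rises with resection size until the seed is effectively isolated;
# the planned (EZ-covering) resection of an SF-like patient reaches a
# comparable decrease at a similar size.
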