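"""Fit the global model parameters (rho, gamma) to seizure patterns.

Generates a small synthetic cohort with recorded-seizure-like patterns at
a known operating point, sweeps the (density, recovery) grid and checks
that the cohort-average goodness of fit peaks near the truth.
"""

import time

from esses import CohortSpec, generate_cohort
from esses.patterns import default_gamma_grid, default_rho_grid, parameter_sweep

rho_grid, gamma_grid = default_rho_grid(), default_gamma_grid()
truth = (8, 10)  # grid indices: rho = 0.133, gamma = 0.658
spec = CohortSpec(
    n_roi=36, n_patients=4, ez_size=5, nsf_fraction=0.0,
    electrode_coverage_fraction=0.8,
    generating_rho=float(rho_grid[truth[0]]),
    generating_gamma=float(gamma_grid[truth[1]]),
    rng_seed=2,
)
patients = generate_cohort(spec, with_patterns=True)

t0 = time.time()
fit = parameter_sweep(
    [p.base_network for p in patients],
    [sorted(p.resection_area) for p in patients],
    [p.ieeg_pattern for p in patients],
    rho_grid, gamma_grid,
    n_realizations=300, n_repetitions=1,
    activity_threshold="expected_extent",
    rng_seed=11,
)
print(f"sweep over {rho_grid.size}x{gamma_grid.size} grid in {time.time() - t0:.0f}s")
print(f"truth:  rho = {rho_grid[truth[0]]:.3f}, gamma = {gamma_grid[truth[1]]:.3f}")
print(f"argmax: rho = {fit.best_point[0]:.3f}, gamma = {fit.best_point[1]:.3f} "
      f"(grid cell {fit.best_index}, C-bar = {fit.c_mean.max():.3f})")
off = max(abs(fit.best_index[0] - truth[0]), abs(fit.best_index[1] - truth[1]))
print(f"argmax is {off} grid cell(s) from the truth "
      "(recovery within one cell is typical at this cohort size)")
# The elevated band of the C-bar surface runs along roughly constant
# rho/gamma — spreading and recovery trade off near the epidemic transition.
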