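"""Expression-fluctuation statistics on a simulated 48-h time lapse.

Generates mean-reverting expression traces (tau = 40 min, sampled every
2 min) for 100 cells and two markers, then recovers the correlation
time from the ensemble autocorrelation and contrasts the overall
(across-cell) with the fluctuation (within-cell) correlation.
"""

import numpy as np
import pandas as pd

from virtustain import simgen, temporal

rng = np.random.default_rng(1)
ou = simgen.OUProcessParams(
    mean_level=1.0, stationary_sd=0.2, correlation_time=40.0,
    frame_interval=2.0, duration=2880.0,
)
n_cells = 100
cell_factor = np.exp(rng.normal(0.0, 0.5, n_cells))  # shared cell-level factor
tr_a = [cell_factor[i] * simgen._ou_trace(ou, rng) for i in range(n_cells)]
tr_b = [cell_factor[i] * simgen._ou_trace(ou, rng) for i in range(n_cells)]

ens = temporal.average_acf([
    temporal.autocorrelation(temporal.TimelapseTrace("c", "A", t, 2.0), max_lag=200)
    for t in tr_a
])
tau = temporal.fit_correlation_time(ens)
print(f"fitted correlation time: {tau:.1f} min (simulated: 40 min)")

r_fluc = [
    float(
        temporal.fluctuation_correlation({
            "A": temporal.TimelapseTrace("c", "A", tr_a[i], 2.0),
            "B": temporal.TimelapseTrace("c", "B", tr_b[i], 2.0),
        }).loc["A", "B"]
    )
    for i in range(n_cells)
]
t_mid = tr_a[0].size // 2
table = pd.DataFrame({
    "mean_A": [t[t_mid] for t in tr_a],
    "mean_B": [t[t_mid] for t in tr_b],
})
r_overall = float(temporal.overall_correlation(table).loc["A", "B"])
print(f"overall correlation (across cells):        {r_overall:.3f}")
print(f"mean fluctuation correlation (within cell): {np.mean(r_fluc):.3f}")
# The shared cell-level factor couples markers across the population,
# but their temporal fluctuations are independent - the same contrast
# seen between population structure and single-cell stochasticity.
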