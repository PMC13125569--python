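"""Estimate spring constants from simulated probe calibration sweeps.

Force–displacement sweeps are linear by Hooke's law; the OLS slope is the
spring constant. With realistic sensor noise the per-post estimates scatter
but their condition mean recovers the ground truth.
"""

import numpy as np

from microtension import fit_spring_constant, summarize_condition
from microtension.synth import simulate_calibration

for label, k_true, max_disp, noise in [("rigid (30:1 PDMS)", 23.5, 170.0, 20.0),
                                       ("compliant (50:1 PDMS)", 1.34, 300.0, 2.0)]:
    curves, _ = simulate_calibration(k_true, np.linspace(0, max_disp, 50),
                                     noise_sd_uN=noise, n_replicates=30,
                                     seed=2, condition=label)
    estimates = [fit_spring_constant(c) for c in curves]
    s = summarize_condition(estimates)
    print(f"{label:22s} truth {k_true:6.2f} → mean k {s['mean_k']:6.3f} "
          f"± {s['sd_k']:5.3f} µN/µm (n = {s['n']})")
print("Each mean sits within a fraction of a percent of the programmed "
      "constant; the SD reflects the probe noise, not estimator bias.")
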