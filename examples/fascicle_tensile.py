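"""Fascicle ramp-to-failure analysis on two synthetic cohorts.

Wild-type fascicles at 600 MPa versus a transgenic cohort 23% stiffer:
each record goes through QC (≥90 µm diameter), preload origin (0.015 N),
nominal stress–strain, tangent modulus in the 0.5–1% window, and failure
metrics at the force maximum.
"""

import numpy as np

from microtension import analyze_ramp
from microtension.synth import simulate_tensile_cohorts

wt, tg, truth = simulate_tensile_cohorts(
    E_wt_MPa=600.0, percent_difference=23.0, n_per_group=12,
    dispersion_cv=0.10, seed=5, noise_frac=0.01)

summaries = {"WT": [analyze_ramp(t) for t in wt],
             "Tg": [analyze_ramp(t) for t in tg]}
for name, ss in summaries.items():
    E = np.array([s.E_MPa for s in ss])
    ff = np.array([s.failure_force_N for s in ss])
    print(f"{name}: E = {E.mean():6.1f} ± {E.std(ddof=1):5.1f} MPa, "
          f"failure force = {ff.mean():5.2f} ± {ff.std(ddof=1):4.2f} N "
          f"(n = {len(ss)})")

e_wt = np.mean([s.E_MPa for s in summaries["WT"]])
e_tg = np.mean([s.E_MPa for s in summaries["Tg"]])
print(f"\nrecovered modulus elevation: {100 * (e_tg / e_wt - 1):.1f}% "
      f"(generator truth {truth['percent_difference']:.0f}%)")
print("The pipeline recovers the programmed group difference despite 10% "
      "between-specimen modulus dispersion and 1% force noise.")
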