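"""Split tissue tension into active and residual components.

Blebbistatin releases the myosin-dependent (active) part of tension; what
remains in the plateau after stimulation is matrix-stored (residual). The
split takes the last pre-stimulation force minus the mean post-stimulation
plateau.
"""

import numpy as np

from microtension import ForceTimecourse, split_active_residual

t = np.linspace(0.0, 48.0, 97)
pre, resid, tau, stim = 300.0, 110.0, 1.5, 40.0
force = np.where(t <= stim, pre,
                 resid + (pre - resid) * np.exp(-(t - stim) / tau))
tc = ForceTimecourse(t, force, k_used=1.34, construct_id="c1")

split = split_active_residual(tc, stim_time_h=stim,
                              plateau_window_h=(stim + 3 * tau, 48.0))
print(f"pre-stimulation tension : {pre:6.1f} µN")
print(f"residual (matrix)       : {split.residual_uN:6.1f} µN")
print(f"active (myosin)         : {split.active_uN:6.1f} µN")
print("\nActive + residual reconstructs the pre-stimulation level; the "
      "plateau window starts 3 relaxation time constants after the drug, so "
      "the residual estimate is within ~2% of the true asymptote.")
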