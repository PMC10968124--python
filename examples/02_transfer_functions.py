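"""Inspect the transfer functions and their time-varying schedules.

Prints the social-force comfort-zone boundary, the catalog values of the
static S/V transfer functions at a few points, and how the alpha/beta/sigma
schedules move the time-varying transfers from exploration to exploitation.
"""

import numpy as np

from grasshopper_fs import (
    TransferSchedule,
    comfort_zone_boundary,
    s_shaped,
    schedules,
    sine_probability,
    tvg_probability,
    v_shaped,
)

print(f"comfort-zone boundary (f=0.5, l=1.5): {comfort_zone_boundary():.3f}")
print("  closer pairs repel, farther pairs attract\n")

x = np.array([-2.0, 0.0, 2.0])
print(f"S1 at {x}: {np.round(s_shaped('s1', x), 4)}  (set-rule probability)")
print(f"V4 at {x}: {np.round(v_shaped('v4', x), 4)}  (flip-rule probability)\n")

sched = TransferSchedule(max_iterations=100)
print("iter   alpha    beta   sigma  |sin(0.5/alpha)|  TVG(0.5)")
for it in (0, 50, 100):
    alpha, beta, sigma = schedules(it, sched)
    p_sine = sine_probability(0.5, alpha)
    p_tvg = tvg_probability(0.5, beta, 0.0, 0.0)   # Gaussian term suppressed
    print(f"{it:4d}  {alpha:6.3f}  {beta:6.3f}  {sigma:6.2f}   "
          f"{p_sine:12.4f}   {p_tvg:8.4f}")

# Early iterations: small alpha makes the sine transfer oscillate fast
# (near-random bits) and the large sigma flips bits aggressively - both
# exploration.  Late iterations: the transfers become smooth and the mutation
# vanishes, so masks settle near the incumbent best solution.
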