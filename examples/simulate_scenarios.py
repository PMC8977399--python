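"""The four shipped miscalibration archetypes.

Each scenario draws true risks from a three-component Beta mixture,
outcomes from Bernoulli(p), and distorts the score with a monotone
piecewise-cubic map.  This prints where each map over- or under-states
risk relative to the threshold R = 0.3.
"""

import numpy as np

import snbrecal as sr

grid = np.array([0.05, 0.30, 0.70])
for name in ("example1", "example2", "example3", "example4"):
    spec = sr.make_scenario(name)
    s = sr.apply_miscalibration(grid, spec)
    frame = sr.simulate_cohort(spec, n=20_000, seed=11)
    direction = ["over" if si > pi else "under" for si, pi in zip(s, grid)]
    print(f"{name}: E[Y]={spec.expected_event_rate:.3f} "
          f"observed event rate={frame['y'].mean():.3f}")
    for p, si, d in zip(grid, s, direction):
        print(f"   true risk {p:.2f} -> score {si:.3f} ({d}estimated)")
# example1: under near R, over elsewhere;  example2: under everywhere;
# example3: over near R, under far;        example4: over everywhere.
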