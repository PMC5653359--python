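"""Score flume trial logs into maximum resisted velocities.

Each snail faces three 4-second flushes per valve level, escalating up the
velocity ladder (0.75, 1.42, 1.88, 2.54, 2.69 m/s) until dislodged, twice.
The snail's resistance is the highest fully-survived level's velocity over
the two rounds; analyses use its square (drag scales with velocity squared).
"""

import pandas as pd

from wavecline import max_resisted_velocity
from wavecline.traits import FlumeConfig

config = FlumeConfig()
print("velocity ladder:", config.ladder, "m/s")

examples = {
    "resists level 3, dislodged at 4 (both rounds)": [
        (r, lvl, fl, False) for r in (1, 2) for lvl in (1, 2, 3) for fl in (1, 2, 3)
    ] + [(r, 4, 1, True) for r in (1, 2)],
    "survives the whole ladder": [
        (r, lvl, fl, False) for r in (1, 2) for lvl in range(1, 6) for fl in (1, 2, 3)
    ],
    "round 1 fails level 1, round 2 resists level 2": [
        (1, 1, 1, True)] + [(2, lvl, fl, False) for lvl in (1, 2) for fl in (1, 2, 3)
    ] + [(2, 3, 1, True)],
}

for label, rows in examples.items():
    log = pd.DataFrame(sorted(rows), columns=["round", "level", "flush", "dislodged"])
    s = max_resisted_velocity(log, config)
    print(f"\n{label}:\n  max velocity {s.max_velocity:.2f} m/s, "
          f"SFR {s.sfr:.3f} m^2/s^2, censoring: {s.censoring}")
print("\n'right' censoring marks snails stronger than the flume's top speed; "
      "'left' marks snails that never held on at the lowest level (scored 0).")
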