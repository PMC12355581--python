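"""The two SpO2 sudden-drop rules on analytic traces.

A desaturation event must (1) drop at least 3% and (2) fall faster than
k0 = 0.001 saturation fraction per second.  Three piecewise-linear traces
show an accepted drop, a slope rejection and a depth rejection.
"""

import numpy as np

from lrsahs import SampledSignal, detect_drops


def trace(bp, vals, dur):
    t = np.arange(int(dur * 10)) / 10.0
    return SampledSignal(np.interp(t, bp, vals), rate=10.0, kind="spo2")


cases = {
    "5% fall over 20 s, 10-s valley": trace(
        [0, 60, 80, 89.9, 90, 150], [0.98, 0.98, 0.93, 0.93, 0.98, 0.98], 150),
    "3% fall over 60 s (too slow)": trace(
        [0, 60, 120, 125, 300], [0.98, 0.98, 0.95, 0.98, 0.98], 300),
    "2% fall over 5 s (too shallow)": trace(
        [0, 60, 65, 75, 80, 300], [0.98, 0.98, 0.96, 0.96, 0.98, 0.98], 300),
}

for label, sig in cases.items():
    events = detect_drops(sig)
    if events:
        ev = events[0]
        print(f"{label}: ACCEPTED  depth={ev.depth:.3f}  slope={ev.slope:.4f}/s  "
              f"duration={ev.duration_s:.1f} s (= (t2-t1) + valley dwell)")
    else:
        print(f"{label}: rejected")
# Only the first trace satisfies both rules; its duration combines the
# 20-s fall with the 10-s valley dwell, giving a 30-s event.
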