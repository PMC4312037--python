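#!/usr/bin/env python
"""Simulate prospectively dual-gated scan schedules at the cohort's
physiological rates (cardiac 420 bpm, respiration 108 bpm) and measure
total scan time against the 286 s frame-rate floor.

Finding: with gating vacuous the 286-projection scan takes exactly 286 s.
Under dual gating with a 30% end-exhalation window the simulated scans
take ~320-330 s: the 167 ms plateau is wider than one R-R interval
(143 ms), so nearly every respiratory cycle offers a valid beat and the
trigger rule waits far less than the ~10 min the real hardware needed —
see docs/methods.md for why the simple rule underestimates real overhead.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from murine_dce_quant import gating

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    rows = []
    for seed in range(20):
        trace = gating.simulate_physio(420.0, 108.0, 0.05, 1200.0, seed=seed,
                                       plateau_fraction=0.3)
        sched = gating.schedule_projections(trace, gating.GatingConfig())
        rows.append({"seed": seed,
                     "scan_time_s": round(sched.total_time_s, 2),
                     "rejected_respiratory": sched.n_rejected_resp,
                     "rejected_frame_rate": sched.n_rejected_frame})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "gating_scan_times.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nmedian gated scan time: {np.median(df.scan_time_s):.0f} s "
          f"(frame-rate floor 286 s)")


if __name__ == "__main__":
    main()
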