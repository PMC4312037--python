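#!/usr/bin/env python
"""Calibrate mono-exponential contrast washout curves for blood, infarct
and viable myocardium from the two measured enhancement time points
(411/431/182 HU at 13 min; 245/281/139 HU at 30 min), and tabulate the
fitted kinetics.

Finding: blood clears fastest (lambda ~ 0.030 /min) and the infarct
retains contrast (lambda ~ 0.025 /min) while remaining ~250 HU above
viable myocardium at the first acquisition — the window that makes delayed
enhancement segmentable.
"""

from pathlib import Path

import pandas as pd

from murine_dce_quant import phantom

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    t0, t1 = phantom.IOHEXOL_TIMES_MIN
    rows = []
    for tissue, (hu_early, hu_late) in phantom.IOHEXOL_HU.items():
        curve = phantom.calibrate_washout(hu_early, hu_late, t0, t1)
        rows.append({
            "tissue": tissue,
            "hu_13min": hu_early, "hu_30min": hu_late,
            "a0_hu": round(curve.a0_hu, 2),
            "lambda_per_min": round(curve.rate_per_min, 5),
            "check_hu_13": round(curve.hu(t0), 3),
            "check_hu_30": round(curve.hu(t1), 3),
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "washout_calibration.csv", index=False)
    print(df.to_string(index=False))
    contrast = (phantom.IOHEXOL_HU["infarct"][0]
                - phantom.IOHEXOL_HU["myocardium"][0])
    print(f"\ninfarct-vs-myocardium contrast at 13 min: {contrast:.0f} HU")


if __name__ == "__main__":
    main()
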