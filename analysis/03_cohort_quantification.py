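#!/usr/bin/env python
"""Run the full synthetic study: an 8-subject ischemia-reperfusion cohort
(subject 5 motion-corrupted) plus 7 controls, imaged, segmented and
quantified through both the CT and histology arms.

Finding: clean subjects recover their ground-truth infarct percentage
within ~1 point in both arms; the motion-corrupted subject's CT estimate
is displaced by several points, and the IR group's ejection fraction sits
well below the controls'.
"""

from pathlib import Path

from murine_dce_quant import pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main():
    config = pipeline.RunConfig(seed=17, out_dir=str(OUT))
    result = pipeline.run_all(config)
    print(result.subject_table.to_string(index=False))
    rep = result.report
    print(f"\nCT vs histology: R^2(all) = {rep.r2_all:.4f}, "
          f"R^2(excluding motion subject {rep.excluded_ids}) = "
          f"{rep.r2_excluded:.4f}")
    print(f"IR-vs-control EF Welch test: p = {result.group_ef_p:.2g}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
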