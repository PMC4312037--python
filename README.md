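# murine-dce-quant

Quantification of myocardial infarction in the mouse from
delayed-contrast-enhanced, prospectively gated cardiac micro-CT — with a
matched TTC-histology arm and the cross-modality statistics that validate
the CT measurements. Because no raw scans from such studies are publicly
deposited, the package ships a first-class synthetic-data generator
(digital heart phantoms, physiological traces, stained-slice photographs)
so every stage of the pipeline can be exercised and tested end to end with
known ground truth.

It is aimed at preclinical cardiac imaging groups who want a tested,
scriptable reference implementation of this quantification chain, and at
methods developers who need phantoms with analytic oracles.

## What it computes

**Contrast kinetics.** Each tissue's enhancement follows a mono-exponential
washout `HU(t) = A0 · exp(−λt)`, calibrated exactly through two measured
time points. At 13 min after an Iohexol bolus the phantom tissues sit at
411 HU (blood), 431 HU (infarct) and 182 HU (viable myocardium); at 30 min
at 245/281/139 HU. Necrotic myocardium retains the extracellular agent —
the "delayed enhancement" that makes the infarct segmentable.

**Prospective dual gating.** A projection is exposed only when the whole
15 ms exposure sits in the end-exhalation plateau, starts at a fixed delay
after an ECG R-wave (0 ms ≈ diastole, 55 ms ≈ systole), and the 1 Hz
flat-panel detector has read out the previous frame. The scheduler turns
simulated ECG/respiration (420 ± 70 and 108 ± 17 bpm) into trigger times,
gantry angles over a 200° arc (286 projections) and the total scan time,
whose unconstrained floor is exactly 286 s.

**CT quantification.** The LV blood pool is segmented by seeded,
threshold-constrained region growing; ventricular volumes are voxel counts
times spacing³, and

```
EF = (V_dia − V_sys) / V_dia .
```

The myocardium is the uniform band dilated from the blood pool; infarct is
delayed hyper-enhancement above `T = μ̂ + k·σ̂` where μ̂, σ̂ are robust
(lower-tail, truncated-normal-corrected) statistics of the myocardial HU
distribution. Infarct size is reported as a percentage of the LV
myocardium.

**Histology quantification.** TTC-stained 1 mm slices are photographed on
both faces; pale (low-saturation, high-luma) pixels within the tissue mask
are infarct, and front/back areas are averaged per slab before integrating
to a volume percentage — a ratio immune to tissue shrinkage.

**Agreement statistics.** Pearson R² between the two arms with explicit
outlier exclusion, a paired t-test for systematic offset, and a Welch test
for group EF differences. On the study's printed eight-subject table the
package reproduces R² = 0.6897 (all subjects) and 0.8329 after excluding
the motion-corrupted subject 5.

## Worked example

```python
import dataclasses
from murine_dce_quant import phantom, ct_quant, pipeline, histo_quant

spec = phantom.PhantomSpec.from_ef(0.36, infarct_wedge=(-100.0, 44.0, 0.75),
                                   seed=11)

dia, labels = phantom.build_heart_phantom(spec, "diastole", 5.0,
                                          washout=spec.washout_blood_pool)
sys_, _ = phantom.build_heart_phantom(spec, "systole", 5.0,
                                      washout=spec.washout_blood_pool)
delayed, _ = phantom.build_heart_phantom(spec, "diastole", 13.0)

out = pipeline.quantify_ct_subject(dia, sys_, delayed,
                                   ct_quant.SegmentationParams())
slices = phantom.render_ttc_slices(spec, thickness_mm=1.0,
                                   pixel_size_mm=0.02, seed=3)
measured = [histo_quant.measure_slice(s) for s in slices]
hist_pct = histo_quant.percent_infarct_histology(measured, 1.0)
```

prints, via the obvious format calls:

```
V_dia = 55.3 mm^3, V_sys = 35.4 mm^3, EF = 0.360
CT infarct: 31.5 % of LV myocardium
histology infarct: 32.3 %
ground truth: 31.5 %
```

i.e. a noisy (30 HU SD) phantom built at true EF 0.36 with a 31.5% infarct
is recovered to 3 decimal places in EF, exactly by the CT arm and within
one point by the simulated histology arm.

The numbered scripts under `analysis/` run the study-level narratives:
washout calibration (`01`), gated scan-time simulation (`02`), the full
15-subject cohort through both arms (`03`), and the agreement statistics
on the printed per-subject table (`04`). Each writes its tables under
`results/`. The same stages are exposed as CLI subcommands
(`murine-dce-quant simulate | gate | quantify-ct | quantify-histology |
compare | run-all`).

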