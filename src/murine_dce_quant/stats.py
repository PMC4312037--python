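"""Cross-modality (CT vs histology) and cross-group agreement statistics.

Includes the study's per-subject infarct table, Pearson R^2 with explicit
outlier exclusion (the motion-corrupted subject is removed by ID, not by an
automated rule), a paired t-test for method similarity, and a Welch t-test
for the ejection-fraction group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SubjectRecord",
    "AgreementReport",
    "DegenerateTestError",
    "table1_records",
    "mean_sd",
    "pearson_r2",
    "paired_test",
    "group_test",
    "agreement_report",
]


class DegenerateTestError(ValueError):
    """A test statistic is undefined (zero variance where variance is needed)."""


@dataclass
class SubjectRecord:
    """One subject's per-modality infarct percentages and LV volumes."""

    subject_id: int
    group: str = "IR"
    ct_infarct_pct: float | None = None
    hist_infarct_pct: float | None = None
    v_dia_mm3: float | None = None
    v_sys_mm3: float | None = None
    ef: float | None = None
    motion_artifact: bool = False

    def __post_init__(self):
        for pct in (self.ct_infarct_pct, self.hist_infarct_pct):
            if pct is not None and not (0.0 <= pct <= 100.0):
                raise ValueError(f"percentages must lie in [0, 100], got {pct}")


@dataclass
class AgreementReport:
    """CT-vs-histology agreement over a cohort."""

    n: int
    mean_ct: float
    sd_ct: float
    mean_hist: float
    sd_hist: float
    r2_all: float
    r2_excluded: float
    excluded_ids: tuple[int, ...]
    paired_p: float
    differences: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_ids"] = list(self.excluded_ids)
        return d


# Per-subject percent infarct of the LV wall, (CT, histology), as printed in
# the study's comparison table; subject 5's CT estimate was corrupted by
# motion streaks near the ribs.
_TABLE1 = [
    (1, 24.8, 20.2), (2, 32.7, 33.2), (3, 13.3, 20.6), (4, 35.7, 36.5),
    (5, 37.6, 26.2), (6, 34.0, 33.8), (7, 27.0, 30.9), (8, 52.7, 42.5),
]
MOTION_ARTIFACT_SUBJECT_ID = 5


def table1_records() -> list[SubjectRecord]:
    """The eight printed CT/histology infarct percentage pairs."""
    return [SubjectRecord(subject_id=i, group="IR", ct_infarct_pct=ct,
                          hist_infarct_pct=hist,
                          motion_artifact=(i == MOTION_ARTIFACT_SUBJECT_ID))
            for i, ct, hist in _TABLE1]


def mean_sd(values: Sequence[float], ddof: int = 1) -> tuple[float, float]:
    """Arithmetic mean and SD with divisor n - ddof (default sample SD)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values for a standard deviation")
    if ddof not in (0, 1):
        raise ValueError("ddof must be 0 or 1")
    return float(v.mean()), float(v.std(ddof=ddof))


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("correlation undefined for zero variance")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


def paired_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on the per-subject differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0  # identical lists: no evidence of difference
        raise DegenerateTestError(
            "constant nonzero difference: paired t statistic undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def group_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) two-sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise DegenerateTestError(
            "both groups constant with different means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def agreement_report(records: Iterable[SubjectRecord],
                     exclude_ids: Iterable[int] = ()) -> AgreementReport:
    """Assemble cross-modality statistics over subjects with both
    measurements; ``r2_excluded`` drops the listed subject IDs."""
    usable = [r for r in records
              if r.ct_infarct_pct is not None and r.hist_infarct_pct is not None]
    if len(usable) < 2:
        raise ValueError("need at least two subjects with both measurements")
    exclude = tuple(sorted(set(int(i) for i in exclude_ids)))
    ct = [r.ct_infarct_pct for r in usable]
    hist = [r.hist_infarct_pct for r in usable]
    kept = [r for r in usable if r.subject_id not in exclude]
    if len(kept) < 2:
        raise ValueError("exclusion leaves fewer than two subjects")
    mean_ct, sd_ct = mean_sd(ct)
    mean_hist, sd_hist = mean_sd(hist)
    r2_all = pearson_r2(ct, hist)
    r2_excluded = (r2_all if not exclude else
                   pearson_r2([r.ct_infarct_pct for r in kept],
                              [r.hist_infarct_pct for r in kept]))
    _, paired_p = paired_test(ct, hist)
    diffs = {r.subject_id: r.ct_infarct_pct - r.hist_infarct_pct
             for r in usable}
    return AgreementReport(n=len(usable), mean_ct=mean_ct, sd_ct=sd_ct,
                           mean_hist=mean_hist, sd_hist=sd_hist,
                           r2_all=r2_all, r2_excluded=r2_excluded,
                           excluded_ids=exclude, paired_p=paired_p,
                           differences=diffs)
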