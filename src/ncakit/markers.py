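"""Pharmacodynamic computations: expression-normalization marker
selection, PNC prevalence comparison, and exposure–response correlation.

The marker filter looks for transcripts whose dysregulation in
PNC-containing tumors is "normalized" by treatment while the PNC-free
normal pancreas stays unperturbed.  With signed fold changes (an x-fold
down-regulation encoded as −x), a transcript qualifies when the
treatment response in tumor is large (|fc_tm_tv| ≥ 3), the normal-pancreas
response is small (|fc_pm_pv| < 2), the treatment response points back
toward the normal-pancreas baseline (fc_tm_tv · fc_pv_tv > 9, which also
enforces sign concordance), and the change is significant (p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConventionError, InsufficientDataError, ValidationError
from .profiles import FoldChangeRecord, PncCellCounts

__all__ = [
    "MarkerSelectionCriteria",
    "ExposureResponsePoint",
    "ExposureResponseFit",
    "select_markers",
    "pnc_prevalence",
    "compare_prevalence",
    "exposure_response",
]


@dataclass(frozen=True)
class MarkerSelectionCriteria:
    """Thresholds of the normalization filter (defaults as published)."""

    min_abs_fc_tm_tv: float = 3.0
    max_abs_fc_pm_pv: float = 2.0
    min_product_tm_tv_by_pv_tv: float = 9.0
    max_p_value: float = 0.001

    def __post_init__(self) -> None:
        for name in (
            "min_abs_fc_tm_tv",
            "max_abs_fc_pm_pv",
            "min_product_tm_tv_by_pv_tv",
            "max_p_value",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")


def select_markers(
    records: Sequence[FoldChangeRecord],
    criteria: MarkerSelectionCriteria = MarkerSelectionCriteria(),
) -> list[str]:
    """Apply the normalization filter; returns gene ids in input order.

    A gene passes iff |fc_tm_tv| ≥ 3 AND |fc_pm_pv| < 2 AND
    fc_tm_tv·fc_pv_tv > 9 AND p < 0.001 (inequality strictness as stated;
    thresholds configurable via ``criteria``).  Inputs must use the signed
    convention — any |fold change| < 1 indicates ratio encoding and raises
    :class:`ConventionError`.
    """
    for r in records:
        for name in ("fc_tm_tv", "fc_pm_pv", "fc_pv_tv"):
            if abs(getattr(r, name)) < 1.0:
                raise ConventionError(
                    f"{r.gene_id}: {name}={getattr(r, name)} looks "
                    "ratio-encoded; use signed fold changes (down x -> -x)"
                )
    c = criteria
    return [
        r.gene_id
        for r in records
        if abs(r.fc_tm_tv) >= c.min_abs_fc_tm_tv
        and abs(r.fc_pm_pv) < c.max_abs_fc_pm_pv
        and r.fc_tm_tv * r.fc_pv_tv > c.min_product_tm_tv_by_pv_tv
        and r.p_value < c.max_p_value
    ]


def pnc_prevalence(counts: Sequence[PncCellCounts], group: str) -> float:
    """Mean PNC prevalence of a group: per-sample fraction of cells with
    ≥1 PNC, averaged unweighted across samples."""
    per_sample = [c.prevalence for c in counts if c.group == group]
    if not per_sample:
        raise InsufficientDataError(f"no samples in group {group!r}")
    return float(np.mean(per_sample))


def compare_prevalence(
    vehicle: Sequence[PncCellCounts],
    treated: Sequence[PncCellCounts],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample two-tailed t test on per-sample PNC prevalences.

    Returns (mean difference treated − vehicle, p value).  Equal-variance
    (Student) by default; ``equal_var=False`` for Welch.  When both groups
    are constant with equal means the test is vacuous and p = 1.
    """
    v = np.array([c.prevalence for c in vehicle], dtype=float)
    t = np.array([c.prevalence for c in treated], dtype=float)
    if v.size < 2 or t.size < 2:
        raise InsufficientDataError("need >= 2 samples per group")
    diff = float(t.mean() - v.mean())
    if v.std() == 0.0 and t.std() == 0.0:
        return diff, 1.0 if diff == 0.0 else 0.0
    res = stats.ttest_ind(t, v, equal_var=equal_var)
    return diff, float(res.pvalue)


@dataclass(frozen=True)
class ExposureResponsePoint:
    """One cohort: intratumor exposure vs marker expression (qRT-PCR,
    reference-gene normalized)."""

    cohort_id: str
    auc_0_24: float  # ng·h/mL
    relative_expression: float

    def __post_init__(self) -> None:
        if self.auc_0_24 < 0:
            raise ValidationError("auc_0_24 must be >= 0")
        if not self.relative_expression > 0:
            raise ValidationError("relative_expression must be > 0")


@dataclass(frozen=True)
class ExposureResponseFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def exposure_response(points: Sequence[ExposureResponsePoint]) -> ExposureResponseFit:
    """Least-squares fit of relative expression on AUC0–24h exposure with
    the two-tailed significance of the correlation."""
    if len(points) < 3:
        raise InsufficientDataError("need >= 3 cohorts")
    x = np.array([p.auc_0_24 for p in points], dtype=float)
    y = np.array([p.relative_expression for p in points], dtype=float)
    if np.all(x == x[0]):
        raise ValidationError("exposure is constant across cohorts")
    res = stats.linregress(x, y)
    return ExposureResponseFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(points),
    )
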