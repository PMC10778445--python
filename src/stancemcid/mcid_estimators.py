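"""Anchor-based and distribution-based MCID estimators.

Four anchor-based estimators reference the external anchor grouping:

* **AC** (average change) — mean change score of the "somewhat better"
  group.
* **CD** (change difference) — AC of the "somewhat better" group minus
  the mean change of "the same" group.
* **MDC** (minimum detectable change) — the lower bound of the
  confidence interval (default 95%) for the mean change of "the same"
  group: the smallest change beyond measurement error, given that
  improvement is a *reduction* in score.
* **ROC cutoff** — the Youden-optimal change-score threshold separating
  the two groups (delegated to :mod:`stancemcid.roc_analysis`).

Two distribution-based estimators use score dispersion alone:

* **effect size** — ``0.2 × SD`` (a small effect); by default the SD of
  the baseline (T0) scores.
* **SEM** — ``SD × sqrt(1 − r)`` with ``r`` the instrument's
  test–retest reliability.  ``r`` must be supplied by the user; no
  default is shipped.

Anchor-based estimates carry the improvement sign (negative = better);
distribution-based ones are reported as ± magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_anchor import GROUP_BETTER, GROUP_SAME
from .exceptions import EstimationError, ValidationError
from .roc_analysis import ROCResult, roc_curve

SD_SOURCES = ("t0", "d15", "change")


@dataclass(frozen=True)
class ReliabilityInput:
    """User-supplied test–retest reliability coefficient.

    The SEM formula needs the instrument's reliability ``r``; the value
    comes from an external repeatability study and must be cited via
    ``source``.
    """

    r: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValidationError(f"reliability r={self.r} outside [0, 1]")


@dataclass(frozen=True)
class GroupChangeSummary:
    """Per-group score summary (a row of the groups table)."""

    group: str
    n: int
    mean_t0: float
    sd_t0: float
    mean_d15: float
    sd_d15: float
    mean_change: float
    sd_change: float


@dataclass(frozen=True)
class MCIDEstimateSet:
    """The six MCID estimates for one measurement.

    ``ac``, ``cd``, ``mdc`` and ``roc_cutoff`` are signed (negative
    denotes improvement); ``effect_size_mcid`` and ``sem_mcid`` are
    non-negative magnitudes.  ``sem_mcid`` is None when no reliability
    coefficient was supplied.
    """

    measurement: str
    ac: float
    cd: float
    mdc: float
    roc_cutoff: float
    roc_auc: float
    effect_size_mcid: float
    sem_mcid: Optional[float]


def average_change(changes: Sequence[float]) -> float:
    """Mean change score of the "somewhat better" group (AC)."""
    arr = np.asarray(changes, dtype=float)
    if arr.size == 0:
        raise EstimationError("average change undefined for an empty group")
    return float(arr.mean())


def change_difference(ac_better: float, ac_same: float) -> float:
    """Difference in average change between the two groups (CD)."""
    return float(ac_better) - float(ac_same)


def minimum_detectable_change(
    changes: Sequence[float],
    confidence: float = 0.95,
    use_z: bool = False,
) -> float:
    """Lower confidence bound on the stable group's mean change (MDC).

    With improvement defined as a reduction, the smallest change beyond
    measurement error is the lower limit of the two-sided confidence
    interval for the mean change of "the same" group:
    ``mean − q × sd / sqrt(n)`` with ``q`` the Student-t quantile at
    ``(1 + confidence) / 2`` on ``n − 1`` degrees of freedom (a normal
    quantile when ``use_z``).
    """
    arr = np.asarray(changes, dtype=float)
    if arr.size < 2:
        raise EstimationError(
            f"minimum detectable change needs n >= 2 changes, got {arr.size}"
        )
    if not 0.0 < confidence < 1.0:
        raise ValidationError(f"confidence {confidence} outside (0, 1)")
    q = (1.0 + confidence) / 2.0
    crit = stats.norm.ppf(q) if use_z else stats.t.ppf(q, df=arr.size - 1)
    return float(arr.mean() - crit * arr.std(ddof=1) / np.sqrt(arr.size))


def effect_size_mcid(sd: float, multiplier: float = 0.2) -> float:
    """Distribution-based MCID as a small effect: ``multiplier × SD``."""
    if sd < 0:
        raise ValidationError(f"standard deviation {sd} must be non-negative")
    return float(multiplier * sd)


def sem_mcid(sd: float, reliability: ReliabilityInput | float) -> float:
    """Standard error of measurement: ``SD × sqrt(1 − r)``."""
    if sd < 0:
        raise ValidationError(f"standard deviation {sd} must be non-negative")
    r = reliability.r if isinstance(reliability, ReliabilityInput) else float(reliability)
    if not 0.0 <= r <= 1.0:
        raise ValidationError(f"reliability r={r} outside [0, 1]")
    return float(sd * np.sqrt(1.0 - r))


def group_summaries(analysis: pd.DataFrame, measurement: str) -> list[GroupChangeSummary]:
    """Per-group score summaries for one measurement of the analysis table."""
    sub = analysis[analysis["measurement"] == measurement]
    out = []
    for group in (GROUP_SAME, GROUP_BETTER):
        g = sub[sub["group"] == group]
        if g.empty:
            continue
        out.append(
            GroupChangeSummary(
                group=group,
                n=len(g),
                mean_t0=float(g["value_t0"].mean()),
                sd_t0=float(g["value_t0"].std(ddof=1)) if len(g) > 1 else 0.0,
                mean_d15=float(g["value_d15"].mean()),
                sd_d15=float(g["value_d15"].std(ddof=1)) if len(g) > 1 else 0.0,
                mean_change=float(g["change"].mean()),
                sd_change=float(g["change"].std(ddof=1)) if len(g) > 1 else 0.0,
            )
        )
    return out


def _dispersion(sub: pd.DataFrame, sd_source: str) -> float:
    if sd_source not in SD_SOURCES:
        raise ValidationError(f"sd_source {sd_source!r} not one of {SD_SOURCES}")
    col = {"t0": "value_t0", "d15": "value_d15", "change": "change"}[sd_source]
    return float(sub[col].std(ddof=1))


def summarize_mcid(
    analysis: pd.DataFrame,
    reliability: ReliabilityInput | float | None = None,
    confidence: float = 0.95,
    sd_source: str = "t0",
    effect_multiplier: float = 0.2,
    use_z: bool = False,
) -> tuple[list[MCIDEstimateSet], dict[str, ROCResult]]:
    """All six MCID estimates for each measurement in the analysis table.

    Parameters
    ----------
    analysis:
        Output of :func:`stancemcid.cohort_anchor.build_analysis_table`
        — one row per analysis unit with ``measurement``, change scores
        and the anchor ``group``.
    reliability:
        Test–retest reliability for the SEM estimator; when None the
        SEM column is left empty.
    sd_source:
        Which dispersion feeds the distribution-based estimators:
        baseline scores (``"t0"``, default), follow-up scores or change
        scores, computed over all analysed units of the measurement.

    Returns
    -------
    (estimates, roc_results):
        One :class:`MCIDEstimateSet` per measurement, and the full
        :class:`~stancemcid.roc_analysis.ROCResult` keyed by
        measurement for curve export.
    """
    estimates: list[MCIDEstimateSet] = []
    rocs: dict[str, ROCResult] = {}
    for measurement in sorted(analysis["measurement"].unique()):
        sub = analysis[analysis["measurement"] == measurement]
        better = sub.loc[sub["group"] == GROUP_BETTER, "change"].to_numpy()
        same = sub.loc[sub["group"] == GROUP_SAME, "change"].to_numpy()
        if better.size == 0 or same.size == 0:
            raise EstimationError(
                f"{measurement}: both anchor groups must be nonempty "
                f"(same n={same.size}, somewhat_better n={better.size})"
            )
        ac = average_change(better)
        cd = change_difference(ac, average_change(same))
        mdc = minimum_detectable_change(same, confidence=confidence, use_z=use_z)
        roc = roc_curve(sub["change"].to_numpy(), sub["group"].to_numpy())
        rocs[measurement] = roc
        sd = _dispersion(sub, sd_source)
        es = effect_size_mcid(sd, multiplier=effect_multiplier)
        sem = None if reliability is None else sem_mcid(sd, reliability)
        estimates.append(
            MCIDEstimateSet(
                measurement=measurement,
                ac=ac,
                cd=cd,
                mdc=mdc,
                roc_cutoff=roc.optimal_cutoff,
                roc_auc=roc.auc,
                effect_size_mcid=es,
                sem_mcid=sem,
            )
        )
    return estimates, rocs
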