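"""ROC analysis of change scores against the anchor grouping.

The "somewhat better" group is the positive class and a *more negative*
change score is the stronger signal of improvement, so the
classification rule is ``change ≤ threshold ⇒ predicted improved``.

Candidate thresholds are the midpoints between consecutive distinct
pooled change values plus one sentinel below the minimum and one above
the maximum, so the reported cutoff is well-defined between data points
rather than sitting on an observation.  The area under the curve is
computed by the rank (Mann–Whitney) method with ties counted half: it
equals the probability that a randomly chosen improved unit shows a
more negative change than a randomly chosen stable unit.

The optimal cutoff maximises the Youden index J = sensitivity +
specificity − 1; ties on J are broken toward the highest sensitivity,
then toward the most negative threshold.  Both tie-breaks are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort_anchor import GROUP_BETTER, GROUP_SAME
from .exceptions import EstimationError, ValidationError


@dataclass(frozen=True)
class ROCResult:
    """ROC curve, rank AUC and Youden-optimal cutoff.

    Attributes
    ----------
    points:
        One row per candidate threshold: ``threshold``, ``sensitivity``,
        ``specificity``, in increasing threshold order.
    auc:
        Rank-method area under the curve (ties half-weighted).
    optimal_cutoff, sensitivity, specificity, youden_j:
        The Youden-optimal operating point (``optimal_cutoff`` is NaN
        when the curve is degenerate).
    degenerate:
        True when all change scores are identical: AUC is 0.5 and no
        cutoff discriminates.
    inverted:
        True when the raw AUC is below 0.5 (the measure points the
        wrong way); the result is flagged rather than silently flipped.
    """

    points: pd.DataFrame
    auc: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    degenerate: bool = False
    inverted: bool = False


def _as_groups(changes, labels) -> tuple[np.ndarray, np.ndarray]:
    changes = np.asarray(changes, dtype=float)
    labels = np.asarray(labels)
    allowed = {GROUP_BETTER, GROUP_SAME}
    bad = set(np.unique(labels)) - allowed
    if bad:
        raise ValidationError(f"labels must be binary {sorted(allowed)}, got extras {sorted(bad)}")
    pos = changes[labels == GROUP_BETTER]
    neg = changes[labels == GROUP_SAME]
    if pos.size == 0 or neg.size == 0:
        raise EstimationError("both anchor groups must be nonempty for ROC analysis")
    return pos, neg


def rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = P(pos change < neg change) + ½ P(tie), via pooled midranks."""
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    s_pos = ranks[: pos.size].sum()
    # pairs where the positive value exceeds a negative one (ties half)
    u_pos_greater = s_pos - pos.size * (pos.size + 1) / 2.0
    return float(1.0 - u_pos_greater / (pos.size * neg.size))


def candidate_thresholds(pooled: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct pooled values, with one
    sentinel below the minimum and one above the maximum."""
    v = np.unique(pooled)
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate([[v[0] - 1.0], mids, [v[-1] + 1.0]])


def roc_curve(changes, labels) -> ROCResult:
    """ROC curve of change scores discriminating improved from stable units.

    Parameters
    ----------
    changes:
        Change scores (follow-up minus baseline; negative = improved).
    labels:
        Group label per unit (``somewhat_better`` = positive class,
        ``same`` = negative class).
    """
    pos, neg = _as_groups(changes, labels)
    pooled = np.concatenate([pos, neg])

    thresholds = candidate_thresholds(pooled)
    # rule: change <= threshold  =>  predicted improved
    sens = (pos[None, :] <= thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] > thresholds[:, None]).mean(axis=1)
    points = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )

    if np.unique(pooled).size == 1:
        return ROCResult(
            points=points,
            auc=0.5,
            optimal_cutoff=float("nan"),
            sensitivity=float("nan"),
            specificity=float("nan"),
            youden_j=0.0,
            degenerate=True,
        )

    auc = rank_auc(pos, neg)
    j = sens + spec - 1.0
    # argmax of J; ties -> highest sensitivity, then most negative threshold
    order = np.lexsort((thresholds, -sens, -j))
    best = order[0]
    return ROCResult(
        points=points,
        auc=auc,
        optimal_cutoff=float(thresholds[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        youden_j=float(j[best]),
        inverted=auc < 0.5,
    )


def youden_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """The Youden-optimal operating point of a fitted curve.

    Returns ``(threshold, sensitivity, specificity)``.
    """
    if roc.degenerate:
        raise EstimationError("no discriminating cutoff: all change scores identical")
    return roc.optimal_cutoff, roc.sensitivity, roc.specificity


def classify_auc(auc: float) -> str:
    """Discriminative-ability label for an AUC value.

    ``unacceptable`` below 0.7, ``acceptable`` in [0.7, 0.8),
    ``excellent`` in [0.8, 0.9), ``outstanding`` at or above 0.9.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValidationError(f"AUC {auc} outside [0, 1]")
    if auc < 0.7:
        return "unacceptable"
    if auc < 0.8:
        return "acceptable"
    if auc < 0.9:
        return "excellent"
    return "outstanding"
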