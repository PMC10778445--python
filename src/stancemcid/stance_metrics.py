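"""Weight-bearing metrics from stance-analyzer trials.

A four-quadrant weight distribution platform reports, for each standing
trial, the percent of body weight borne by each limb.  For a pelvic
(hind) limb the textbook normal share is 20% of body weight, so two
scalar outcome measures summarise hind-limb off-loading:

* **deviation** — ``|20 − wb|`` in percent body-weight points, where
  ``wb`` is the limb's mean weight-bearing share over the session's
  trials.  Zero means normal loading; the absolute value pools limbs
  that under- and over-load (bilateral disease can produce both).
* **symmetry index (SI)** — the normalised left–right difference
  ``|(WBR − WBL) / ((WBR + WBL) / 2)| × 100``; 0 is perfect symmetry
  and the score is invariant to common scaling of the two loads.

Improvement is, by convention, a *reduction* in either score, so change
scores (follow-up minus baseline) are negative when a dog improves.

Trial-level records enter as rows (one per platform reading); this
module validates them, averages the configured number of trials per
session, and emits tidy per-limb and per-dog tables plus change scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientDataError,
    PairingError,
    UndefinedSymmetryIndexError,
    ValidationError,
)

#: Percent body weight a sound pelvic limb is expected to bear.
NORMAL_HIND_LOAD = 20.0

#: Default tolerance (percent points) on the four-limb sum around 100.
DEFAULT_SUM_TOL = 2.0

#: Default number of platform trials required per dog per session.
DEFAULT_MIN_TRIALS = 20

TIMEPOINTS = ("T0", "D15")
SIDES = ("left", "right")

LIMB_COLUMNS = ("wb_lf", "wb_rf", "wb_lh", "wb_rh")


@dataclass(frozen=True)
class TrialMeasurement:
    """One platform reading: percent body weight on each of four limbs."""

    dog_id: str
    timepoint: str
    trial_index: int
    wb_lf: float
    wb_rf: float
    wb_lh: float
    wb_rh: float

    def validate(self, sum_tol: float = DEFAULT_SUM_TOL) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"trial {self.trial_index} of {self.dog_id}: unknown timepoint "
                f"{self.timepoint!r}; expected one of {TIMEPOINTS}"
            )
        loads = [self.wb_lf, self.wb_rf, self.wb_lh, self.wb_rh]
        for name, value in zip(LIMB_COLUMNS, loads):
            if not 0.0 <= value <= 100.0:
                raise ValidationError(
                    f"trial {self.trial_index} of {self.dog_id}: {name}={value} "
                    "outside [0, 100]"
                )
        total = float(sum(loads))
        if not (100.0 - sum_tol) <= total <= (100.0 + sum_tol):
            raise ValidationError(
                f"trial {self.trial_index} of {self.dog_id}: limb loads sum to "
                f"{total:.3f}, outside 100 ± {sum_tol}"
            )


@dataclass(frozen=True)
class LimbTimepoint:
    """Per-limb, per-session aggregate of the hind-limb load."""

    dog_id: str
    side: str
    timepoint: str
    wb_mean: float
    n_trials: int
    deviation: float


@dataclass(frozen=True)
class DogTimepoint:
    """Per-dog, per-session hind-limb means and symmetry index."""

    dog_id: str
    timepoint: str
    wbr: float
    wbl: float
    si: float


@dataclass(frozen=True)
class ChangeScore:
    """Baseline-to-follow-up change for one analysis unit.

    ``change = value_d15 − value_t0``; negative change denotes
    improvement for both deviation and SI.
    """

    unit_id: str
    measurement: str
    value_t0: float
    value_d15: float
    change: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "change", self.value_d15 - self.value_t0)


def compute_deviation(wb_mean: float) -> float:
    """Deviation from the 20% normal hind-limb load, in percent points.

    Parameters
    ----------
    wb_mean:
        Mean percent body weight on the limb, in ``[0, 100]``.

    Returns
    -------
    float
        ``|20 − wb_mean|`` (non-negative; 0 iff the load is exactly
        normal).
    """
    wb = float(wb_mean)
    if not 0.0 <= wb <= 100.0:
        raise ValidationError(f"wb_mean={wb} outside [0, 100]")
    return abs(NORMAL_HIND_LOAD - wb)


def compute_symmetry_index(wbr: float, wbl: float) -> float:
    """Left–right symmetry index of the hind-limb loads.

    ``SI = |(WBR − WBL) / ((WBR + WBL) × 0.5)| × 100``.  Symmetric in
    its arguments and invariant under common positive scaling; ranges
    over ``[0, 200]`` for non-negative loads.
    """
    r, l = float(wbr), float(wbl)
    if r < 0 or l < 0:
        raise ValidationError(f"limb loads must be non-negative, got ({r}, {l})")
    if r + l == 0:
        raise UndefinedSymmetryIndexError(
            "symmetry index undefined: both hind-limb loads are zero"
        )
    return abs((r - l) / ((r + l) * 0.5)) * 100.0


def compute_change(
    value_t0: float | None,
    value_d15: float | None,
    *,
    unit_id: str = "",
    measurement: str = "",
) -> ChangeScore:
    """Pair a unit's two timepoints into a change score (D15 − T0)."""
    if value_t0 is None or value_d15 is None or (
        isinstance(value_t0, float) and np.isnan(value_t0)
    ) or (isinstance(value_d15, float) and np.isnan(value_d15)):
        raise PairingError(
            f"unit {unit_id!r} ({measurement}): both timepoints are required"
        )
    return ChangeScore(unit_id, measurement, float(value_t0), float(value_d15))


def aggregate_trials(
    trials: Sequence[TrialMeasurement],
    min_trials: int = DEFAULT_MIN_TRIALS,
    sum_tol: float = DEFAULT_SUM_TOL,
) -> tuple[LimbTimepoint, LimbTimepoint, DogTimepoint]:
    """Aggregate one dog-session's trials into limb and dog summaries.

    All trials must share ``dog_id`` and ``timepoint``; at least
    ``min_trials`` valid trials are required, and every trial beyond the
    minimum is used (no truncation).  Forelimb values are validated but
    not analysed.

    Returns
    -------
    (left, right, dog):
        :class:`LimbTimepoint` for the left and right hind limbs and a
        :class:`DogTimepoint` with the symmetry index.
    """
    if len(trials) == 0:
        raise InsufficientDataError("no trials supplied")
    dog_id = trials[0].dog_id
    timepoint = trials[0].timepoint
    for t in trials:
        if t.dog_id != dog_id or t.timepoint != timepoint:
            raise ValidationError(
                f"trials mix sessions: ({t.dog_id}, {t.timepoint}) vs "
                f"({dog_id}, {timepoint})"
            )
        t.validate(sum_tol=sum_tol)
    if len(trials) < min_trials:
        raise InsufficientDataError(
            f"{dog_id} at {timepoint}: {len(trials)} trials, "
            f"need at least {min_trials}"
        )
    lh = float(np.mean([t.wb_lh for t in trials]))
    rh = float(np.mean([t.wb_rh for t in trials]))
    n = len(trials)
    left = LimbTimepoint(dog_id, "left", timepoint, lh, n, compute_deviation(lh))
    right = LimbTimepoint(dog_id, "right", timepoint, rh, n, compute_deviation(rh))
    dog = DogTimepoint(dog_id, timepoint, rh, lh, compute_symmetry_index(rh, lh))
    return left, right, dog


def _trials_from_frame(group: pd.DataFrame) -> list[TrialMeasurement]:
    return [
        TrialMeasurement(
            dog_id=str(row.dog_id),
            timepoint=str(row.timepoint),
            trial_index=int(row.trial_index),
            wb_lf=float(row.wb_lf),
            wb_rf=float(row.wb_rf),
            wb_lh=float(row.wb_lh),
            wb_rh=float(row.wb_rh),
        )
        for row in group.itertuples(index=False)
    ]


def aggregate_cohort(
    trials: pd.DataFrame,
    min_trials: int = DEFAULT_MIN_TRIALS,
    sum_tol: float = DEFAULT_SUM_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a whole cohort's trial table.

    Parameters
    ----------
    trials:
        One row per platform trial with columns ``dog_id``,
        ``timepoint`` (T0/D15), ``trial_index`` and the four
        ``wb_*`` limb loads.

    Returns
    -------
    (limb_table, dog_table):
        ``limb_table`` has one row per (dog, side, timepoint) with
        ``wb_mean``, ``n_trials`` and ``deviation``; ``dog_table`` one
        row per (dog, timepoint) with ``wbr``, ``wbl`` and ``si``.
    """
    limb_rows: list[LimbTimepoint] = []
    dog_rows: list[DogTimepoint] = []
    for (_dog, _tp), group in trials.groupby(["dog_id", "timepoint"], sort=True):
        left, right, dog = aggregate_trials(
            _trials_from_frame(group), min_trials=min_trials, sum_tol=sum_tol
        )
        limb_rows.extend([left, right])
        dog_rows.append(dog)
    limb_table = pd.DataFrame([vars(r) for r in limb_rows])
    dog_table = pd.DataFrame([vars(r) for r in dog_rows])
    return limb_table, dog_table


def build_change_table(
    limb_table: pd.DataFrame, dog_table: pd.DataFrame
) -> pd.DataFrame:
    """Tidy change-score table for both measurements.

    Deviation changes are per limb (unit ``dog:side``).  The symmetry
    index is a per-dog quantity; to support limb-level analyses its
    value is replicated onto both of the dog's limbs, and that
    replication is flagged in ``result.attrs["si_replicated"]``.

    Returns a frame with columns ``unit_id, dog_id, measurement,
    value_t0, value_d15, change``.
    """
    rows = []
    wide = limb_table.pivot_table(
        index=["dog_id", "side"], columns="timepoint", values="deviation"
    )
    for (dog_id, side), vals in wide.iterrows():
        cs = compute_change(
            vals.get("T0", np.nan),
            vals.get("D15", np.nan),
            unit_id=f"{dog_id}:{side}",
            measurement="deviation",
        )
        rows.append((cs.unit_id, dog_id, "deviation", cs.value_t0, cs.value_d15, cs.change))

    si_wide = dog_table.pivot_table(index="dog_id", columns="timepoint", values="si")
    for dog_id, vals in si_wide.iterrows():
        cs = compute_change(
            vals.get("T0", np.nan),
            vals.get("D15", np.nan),
            unit_id=str(dog_id),
            measurement="si",
        )
        # dog-level SI replicated onto both limbs (limb-level analysis table)
        for side in SIDES:
            rows.append(
                (f"{dog_id}:{side}", dog_id, "si", cs.value_t0, cs.value_d15, cs.change)
            )

    out = pd.DataFrame(
        rows,
        columns=["unit_id", "dog_id", "measurement", "value_t0", "value_d15", "change"],
    )
    out.attrs["si_replicated"] = True
    return out


def cohort_summary(change_table: pd.DataFrame) -> pd.DataFrame:
    """Whole-cohort summary (one row per measurement): n, T0 and
    follow-up means/SDs of the analysed units."""
    rows = []
    for measurement, grp in change_table.groupby("measurement", sort=True):
        rows.append(
            {
                "measurement": measurement,
                "n": len(grp),
                "mean_t0": grp["value_t0"].mean(),
                "sd_t0": grp["value_t0"].std(ddof=1),
                "mean_d15": grp["value_d15"].mean(),
                "sd_d15": grp["value_d15"].std(ddof=1),
                "mean_change": grp["change"].mean(),
            }
        )
    return pd.DataFrame(rows)


def iter_change_scores(change_table: pd.DataFrame) -> Iterable[ChangeScore]:
    """Yield :class:`ChangeScore` objects from a tidy change table."""
    for row in change_table.itertuples(index=False):
        yield ChangeScore(row.unit_id, row.measurement, row.value_t0, row.value_d15)
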