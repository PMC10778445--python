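"""Anchor-question coding and responder grouping.

The external anchor is the global quality-of-life item of the Canine
Brief Pain Inventory ("How do you describe your dog's overall quality
of life"), answered on a five-level ordinal scale Poor < Fair < Good <
Very Good < Excellent at baseline (T0) and at the 15-day follow-up.

Dogs whose response is unchanged form the "the same" group; dogs whose
follow-up response is exactly one level better form the "somewhat
better" group.  Any other transition (worsening, or a jump of two or
more levels) falls outside the two-group design and is excluded from
MCID estimation; exclusions are counted and logged, never silently
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .exceptions import JoinError, ValidationError

logger = logging.getLogger(__name__)

ANCHOR_LABELS = ("Poor", "Fair", "Good", "Very Good", "Excellent")
_LABEL_TO_LEVEL = {label.lower(): i + 1 for i, label in enumerate(ANCHOR_LABELS)}

GROUP_SAME = "same"
GROUP_BETTER = "somewhat_better"
GROUP_EXCLUDED = "excluded"


def parse_anchor(response: object) -> int:
    """Parse an anchor response into its ordinal level 1..5.

    Accepts the verbal labels (case-insensitive, surrounding whitespace
    ignored) or the numeric codes 1–5.
    """
    if isinstance(response, str):
        key = response.strip().lower()
        if key in _LABEL_TO_LEVEL:
            return _LABEL_TO_LEVEL[key]
        if key.isdigit():
            response = int(key)
        else:
            raise ValidationError(
                f"unknown anchor response {response!r}; allowed labels are "
                f"{ANCHOR_LABELS} or codes 1-5"
            )
    try:
        level = int(response)  # type: ignore[arg-type]
        if level != response:
            raise ValueError
    except (TypeError, ValueError):
        raise ValidationError(
            f"unknown anchor response {response!r}; allowed labels are "
            f"{ANCHOR_LABELS} or codes 1-5"
        ) from None
    if not 1 <= level <= 5:
        raise ValidationError(f"anchor code {level} outside 1-5")
    return level


@dataclass(frozen=True)
class AnchorTransition:
    """Per-dog pair of anchor responses and the derived group label."""

    dog_id: str
    level_t0: int
    level_d15: int

    @property
    def group(self) -> str:
        return classify_transition(self.level_t0, self.level_d15)


def classify_transition(response_t0: object, response_d15: object) -> str:
    """Group label from the T0 → +15 d anchor transition.

    ``same`` when the level is unchanged, ``somewhat_better`` when the
    follow-up response is exactly one level better, ``excluded``
    otherwise.  A total function on the 25 ordered response pairs.
    """
    t0 = parse_anchor(response_t0)
    d15 = parse_anchor(response_d15)
    if d15 == t0:
        return GROUP_SAME
    if d15 == t0 + 1:
        return GROUP_BETTER
    return GROUP_EXCLUDED


def transitions_table(anchors: pd.DataFrame) -> pd.DataFrame:
    """Normalise an anchor frame (dog_id, anchor_t0, anchor_d15) into
    levels and group labels."""
    rows = []
    for row in anchors.itertuples(index=False):
        t0 = parse_anchor(row.anchor_t0)
        d15 = parse_anchor(row.anchor_d15)
        rows.append((str(row.dog_id), t0, d15, classify_transition(t0, d15)))
    return pd.DataFrame(rows, columns=["dog_id", "level_t0", "level_d15", "group"])


def build_analysis_table(
    change_table: pd.DataFrame, anchors: pd.DataFrame
) -> pd.DataFrame:
    """Join change scores with anchor groups; drop excluded dogs.

    Parameters
    ----------
    change_table:
        Tidy change scores (``unit_id, dog_id, measurement, value_t0,
        value_d15, change``) from
        :func:`stancemcid.stance_metrics.build_change_table`.
    anchors:
        One row per dog: ``dog_id, anchor_t0, anchor_d15`` (labels or
        numeric codes).

    Returns
    -------
    pandas.DataFrame
        The change table with a ``group`` column, restricted to the two
        analysis groups.  ``attrs`` carry ``n_excluded_units`` and the
        per-group unit counts.

    Raises
    ------
    JoinError
        If any dog in the change table lacks an anchor record.
    """
    if change_table.empty:
        logger.warning("empty change table: no units to analyse")
        out = change_table.copy()
        out["group"] = pd.Series(dtype=object)
        out.attrs["n_excluded_units"] = 0
        out.attrs["group_sizes"] = {}
        return out
    trans = transitions_table(anchors)
    missing = set(change_table["dog_id"]) - set(trans["dog_id"])
    if missing:
        raise JoinError(
            "dogs with change scores but no anchor record: "
            + ", ".join(sorted(str(d) for d in missing))
        )
    merged = change_table.merge(trans[["dog_id", "group"]], on="dog_id", how="left")
    excluded = merged["group"] == GROUP_EXCLUDED
    n_excluded = int(excluded.sum())
    if n_excluded:
        logger.info(
            "excluding %d unit rows whose anchor transition is outside the "
            "same/somewhat-better design",
            n_excluded,
        )
    out = merged.loc[~excluded].reset_index(drop=True)
    sizes = (
        out.groupby(["measurement", "group"])["unit_id"].count().to_dict()
    )
    logger.info("analysis group sizes: %s", sizes)
    out.attrs["si_replicated"] = change_table.attrs.get("si_replicated", False)
    out.attrs["n_excluded_units"] = n_excluded
    out.attrs["group_sizes"] = sizes
    return out
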