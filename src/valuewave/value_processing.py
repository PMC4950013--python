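"""Questionnaire scoring: ipsatized Schwartz value-type scores and scales.

The Schwartz Value Survey asks for the importance of 56 values on a
quasi-bipolar 9-point scale from -1 (opposed to my values) through 0
(not important) to 7 (of supreme importance).  Each respondent's mean
across all 56 items is subtracted from their raw ratings (ipsatization,
removing rating-style variance), and the centred ratings are averaged
within each of the 10 motivational value types.  Two of the 56 items
belong to no type: they enter the ipsatization mean but no type score.

Also provided: a generic keyed-scale scorer (for trait inventories with
reverse-keyed items) and Cronbach's alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from valuewave.sine_fit import DEFAULT_VALUE_ORDER

RATING_MIN, RATING_MAX = -1, 7

#: Items per value type in the standard 56-item survey (54 assigned, 2 not).
VALUE_TYPE_ITEM_COUNTS: dict[str, int] = {
    "universalism": 7,
    "benevolence": 9,
    "tradition": 6,
    "conformity": 4,
    "security": 6,
    "power": 5,
    "achievement": 6,
    "hedonism": 2,
    "stimulation": 3,
    "self-direction": 6,
}


def validate_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Validate a participants x items rating table.

    Ratings must be integers on the -1..7 scale (the instrument is
    discrete); missing values are allowed but every participant must
    have at least 2 non-missing items.  Returns a float copy with NaN
    for missing.
    """
    df = responses.astype(float)
    vals = df.to_numpy()
    present = ~np.isnan(vals)
    bad_frac = present & (vals != np.round(vals))
    if bad_frac.any():
        i, j = np.argwhere(bad_frac)[0]
        raise ValueError(
            f"non-integer rating {vals[i, j]!r} for participant "
            f"{df.index[i]!r}, item {df.columns[j]!r}"
        )
    out_of_range = present & ((vals < RATING_MIN) | (vals > RATING_MAX))
    if out_of_range.any():
        i, j = np.argwhere(out_of_range)[0]
        raise ValueError(
            f"rating {vals[i, j]} outside [-1, 7] for participant "
            f"{df.index[i]!r}, item {df.columns[j]!r}"
        )
    n_present = present.sum(axis=1)
    if (n_present < 2).any():
        who = list(df.index[n_present < 2])
        raise ValueError(
            f"participants with fewer than 2 non-missing ratings: {who}"
        )
    return df


def ipsatize(responses: pd.DataFrame) -> pd.DataFrame:
    """Centre each participant's ratings on their own mean.

    The mean is taken over that participant's non-missing items; missing
    ratings stay missing.  After centring, every participant's mean over
    non-missing items is 0.
    """
    df = validate_responses(responses)
    return df.sub(df.mean(axis=1, skipna=True), axis=0)


@dataclass(frozen=True)
class ValueItemMap:
    """Assignment of survey items to value types (unassigned allowed)."""

    assignments: Mapping[str, str | None]

    def __post_init__(self):
        object.__setattr__(self, "assignments", dict(self.assignments))

    @property
    def types(self) -> list[str]:
        seen = [t for t in self.assignments.values() if t is not None]
        return sorted(set(seen), key=lambda t: (
            DEFAULT_VALUE_ORDER.index(t) if t in DEFAULT_VALUE_ORDER else 99,
            t,
        ))

    def items_for(self, value_type: str) -> list[str]:
        return [i for i, t in self.assignments.items() if t == value_type]


def default_item_map(item_ids: Sequence[str] | None = None) -> ValueItemMap:
    """The standard 56-item fixture: Table-style counts per type.

    Items are assigned sequentially in the circular type order
    (universalism 7, benevolence 9, tradition 6, conformity 4,
    security 6, power 5, achievement 6, hedonism 2, stimulation 3,
    self-direction 6 = 54 assigned); the final 2 items are unassigned.
    Which 2 survey items are the unassigned ones is instrument lore not
    fixed here, so placeholder ids are used.
    """
    if item_ids is None:
        item_ids = [f"svs{i:02d}" for i in range(1, 57)]
    item_ids = list(item_ids)
    if len(item_ids) != 56:
        raise ValueError("the standard survey has 56 items")
    assignments: dict[str, str | None] = {}
    pos = 0
    for vt in DEFAULT_VALUE_ORDER:
        for _ in range(VALUE_TYPE_ITEM_COUNTS[vt]):
            assignments[item_ids[pos]] = vt
            pos += 1
    while pos < 56:
        assignments[item_ids[pos]] = None
        pos += 1
    return ValueItemMap(assignments)


def aggregate_value_types(
    centered: pd.DataFrame, item_map: ValueItemMap
) -> pd.DataFrame:
    """Average centred ratings within each value type.

    Unassigned items contribute only to the ipsatization mean, never to
    a type score.  A participant with no non-missing item for some type
    is an error (that type's score would be undefined).
    """
    types = item_map.types
    out = pd.DataFrame(index=centered.index, columns=types, dtype=float)
    for vt in types:
        items = [i for i in item_map.items_for(vt) if i in centered.columns]
        if not items:
            raise ValueError(f"no items of type {vt!r} present in the data")
        block = centered[items]
        n_ok = block.notna().sum(axis=1)
        if (n_ok == 0).any():
            who = list(centered.index[n_ok == 0])
            raise ValueError(
                f"participants with no non-missing {vt!r} items: {who}"
            )
        out[vt] = block.mean(axis=1, skipna=True)
    return out


def cronbach_alpha(item_matrix: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha, covariance form.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total
    score), with sample (n-1) variances.  Requires >= 2 items, >= 2
    respondents and a non-degenerate total score.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 respondents")
    if np.isnan(m).any():
        m = m[~np.isnan(m).any(axis=1)]
        if m.shape[0] < 2:
            raise ValueError("fewer than 2 complete respondents")
    k = m.shape[1]
    item_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def alpha_by_type(
    responses: pd.DataFrame, item_map: ValueItemMap
) -> pd.Series:
    """Cronbach's alpha per value type, computed on the raw item ratings."""
    df = validate_responses(responses)
    out = {}
    for vt in item_map.types:
        items = [i for i in item_map.items_for(vt) if i in df.columns]
        out[vt] = cronbach_alpha(df[items])
    return pd.Series(out, name="cronbach_alpha")


@dataclass(frozen=True)
class ScaleSpec:
    """A keyed questionnaire scale: items, reverse-key flags, label."""

    item_ids: tuple[str, ...]
    reverse_keyed: frozenset[str] = field(default_factory=frozenset)
    label: str = "scale"

    def __post_init__(self):
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "reverse_keyed", frozenset(self.reverse_keyed))
        extra = self.reverse_keyed - set(self.item_ids)
        if extra:
            raise ValueError(f"reverse-keyed ids not in the scale: {sorted(extra)}")


def score_scale(
    responses: pd.DataFrame,
    spec: ScaleSpec,
    scale_range: tuple[float, float],
) -> pd.Series:
    """Mean of keyed item ratings per participant.

    Reverse-keyed items are recoded as lo + hi - rating before
    averaging; missing items are excluded from the mean.  A participant
    with every scale item missing is an error.
    """
    lo, hi = scale_range
    missing_items = [i for i in spec.item_ids if i not in responses.columns]
    if missing_items:
        raise KeyError(f"scale items absent from responses: {missing_items}")
    block = responses[list(spec.item_ids)].astype(float)
    for item in spec.reverse_keyed:
        block[item] = lo + hi - block[item]
    n_ok = block.notna().sum(axis=1)
    if (n_ok == 0).any():
        who = list(block.index[n_ok == 0])
        raise ValueError(f"participants with all scale items missing: {who}")
    return block.mean(axis=1, skipna=True).rename(spec.label)


# ---------------------------------------------------------------------------
# file I/O

def read_responses(path, sep: str | None = None) -> pd.DataFrame:
    """Read a ratings table: first column participant id, header item ids."""
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_item_map(path) -> ValueItemMap:
    """Two-column TSV (item_id, value_type), 'NA' marking unassigned items."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    assignments = {
        str(row.iloc[0]): (None if row.iloc[1] == "NA" else str(row.iloc[1]))
        for _, row in df.iterrows()
    }
    return ValueItemMap(assignments)


def write_item_map(item_map: ValueItemMap, path) -> None:
    rows = [
        {"item_id": i, "value_type": t if t is not None else "NA"}
        for i, t in item_map.assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_value_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="participant_id")
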