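"""Scoring of the 39-item Five Facet Mindfulness Questionnaire (FFMQ-39).

The FFMQ measures five facets of trait mindfulness — observing, describing,
acting with awareness, nonjudgment and nonreactivity — from 39 Likert items
rated 1 ("never or very rarely true") to 5 ("very often or always true").
Nonreactivity has 7 items (totals 7–35); each other facet has 8 (totals 8–40).
Reverse-keyed items are scored ``6 - response`` before summation, so higher
totals always mean higher mindfulness.

Scoring rules implemented here:

* missing responses are imputed with the mean of the subject's *observed*
  items within the same subscale, on the scored (reverse-corrected) scale;
* subjects missing strictly more than 10% of the form (i.e. >3.9 of 39 items)
  are excluded from analysis;
* facet totals are column z-scored (sample SD, ``ddof=1``) before entering
  the PLS behaviour block, because the subscales have different ranges.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FACETS",
    "N_ITEMS",
    "SubscaleKey",
    "SubscaleScores",
    "default_key",
    "score_ffmq",
    "impute_subscale_mean",
    "apply_exclusion",
    "standardize_facets",
    "FFMQError",
    "UnimputableError",
]

FACETS = (
    "observing",
    "describing",
    "acting_with_awareness",
    "nonjudgment",
    "nonreactivity",
)
N_ITEMS = 39
LIKERT_MIN, LIKERT_MAX = 1, 5
#: items per subscale implied by the 39-item form
_FACET_SIZES = {f: (7 if f == "nonreactivity" else 8) for f in FACETS}

DEFAULT_EXCLUSION_THRESHOLD = 0.10


class FFMQError(ValueError):
    """Invalid questionnaire input or key."""


class UnimputableError(FFMQError):
    """A retained subject has an entirely missing subscale."""


@dataclass(frozen=True)
class SubscaleKey:
    """Assignment of the 39 items to subscales with reverse-scoring flags.

    Parameters
    ----------
    subscale : mapping of item name -> facet name
    reverse : mapping of item name -> bool
        True where the item is reverse-keyed (scored ``6 - response``).
    """

    subscale: Mapping[str, str]
    reverse: Mapping[str, bool]

    def __post_init__(self) -> None:
        items = list(self.subscale)
        if len(items) != N_ITEMS:
            raise FFMQError(f"key must cover exactly {N_ITEMS} items, got {len(items)}")
        if set(items) != set(self.reverse):
            raise FFMQError("subscale and reverse maps cover different items")
        unknown = set(self.subscale.values()) - set(FACETS)
        if unknown:
            raise FFMQError(f"unknown subscales in key: {sorted(unknown)}")
        for facet, size in _FACET_SIZES.items():
            n = sum(1 for f in self.subscale.values() if f == facet)
            if n != size:
                raise FFMQError(f"{facet} must have {size} items, got {n}")

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.subscale)

    def items_for(self, facet: str) -> tuple[str, ...]:
        return tuple(i for i, f in self.subscale.items() if f == facet)

    def min_score(self, facet: str) -> int:
        return _FACET_SIZES[facet] * LIKERT_MIN

    def max_score(self, facet: str) -> int:
        return _FACET_SIZES[facet] * LIKERT_MAX

    def max_scoring_sheet(self, subjects: Iterable[str] = ("s1",)) -> pd.DataFrame:
        """Response sheet attaining the maximum total on every subscale.

        Straight items get the top Likert option (5); reverse-keyed items get
        the bottom option (1), which scores as 5 after reverse correction.
        """
        row = {i: (LIKERT_MIN if self.reverse[i] else LIKERT_MAX) for i in self.items}
        idx = pd.Index(list(subjects), name="subject")
        return pd.DataFrame([row] * len(idx), index=idx, dtype=float)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubscaleKey":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "SubscaleKey":
        items = raw["items"]
        return cls(
            subscale={k: v["subscale"] for k, v in items.items()},
            reverse={k: bool(v["reverse"]) for k, v in items.items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "items": {
                i: {"subscale": self.subscale[i], "reverse": bool(self.reverse[i])}
                for i in self.items
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def default_key() -> SubscaleKey:
    """The shipped FFMQ-39 key (published item assignment)."""
    ref = resources.files("mindpls.data") / "ffmq_key.yaml"
    with ref.open() as fh:
        return SubscaleKey._from_mapping(yaml.safe_load(fh))


@dataclass
class SubscaleScores:
    """Per-subject subscale totals plus exclusion bookkeeping.

    Attributes
    ----------
    scores : DataFrame (subjects x 5 facets)
        Totals on the raw questionnaire scale; NaN rows for excluded subjects.
    excluded : boolean Series per subject
    n_missing : integer Series, count of originally missing items per subject
    """

    scores: pd.DataFrame
    excluded: pd.Series
    n_missing: pd.Series
    threshold: float = DEFAULT_EXCLUSION_THRESHOLD

    @property
    def included(self) -> pd.DataFrame:
        """Totals for retained subjects only."""
        return self.scores.loc[~self.excluded]


def _validate_items(items: pd.DataFrame, key: SubscaleKey) -> pd.DataFrame:
    missing_cols = [i for i in key.items if i not in items.columns]
    if missing_cols:
        raise FFMQError(f"response table lacks item columns: {missing_cols}")
    out = items[list(key.items)].astype(float)
    bad = (out.notna()) & ((out < LIKERT_MIN) | (out > LIKERT_MAX))
    if bad.to_numpy().any():
        subj, item = next(
            (s, i) for s in out.index for i in out.columns if bad.at[s, i]
        )
        raise FFMQError(
            f"response out of range 1..5 for subject {subj!r}, item {item!r}: "
            f"{out.at[subj, item]}"
        )
    return out


def _reverse(items: pd.DataFrame, key: SubscaleKey) -> pd.DataFrame:
    """Map responses to the scored scale (reverse-keyed items -> 6 - value)."""
    scored = items.copy()
    rev = [i for i in key.items if key.reverse[i]]
    scored[rev] = 6.0 - scored[rev]
    return scored


def impute_subscale_mean(items: pd.DataFrame, key: SubscaleKey | None = None) -> pd.DataFrame:
    """Fill missing responses with the subject's own subscale mean.

    Imputation happens on the scored (reverse-corrected) scale and is mapped
    back, so the returned table is on the raw response scale with observed
    cells untouched.  Raises :class:`UnimputableError` if a subject has an
    entirely missing subscale.
    """
    key = key or default_key()
    items = _validate_items(items, key)
    scored = _reverse(items, key)
    filled = scored.copy()
    for facet in FACETS:
        cols = list(key.items_for(facet))
        block = scored[cols]
        holes = block.isna()
        if not holes.to_numpy().any():
            continue
        means = block.mean(axis=1, skipna=True)
        empty = means.isna() & holes.any(axis=1)
        if empty.any():
            subj = empty.idxmax()
            raise UnimputableError(
                f"subject {subj!r} has no observed responses on subscale {facet!r}"
            )
        filled[cols] = block.apply(lambda col: col.fillna(means))
    # back to the raw response scale
    raw = filled.copy()
    rev = [i for i in key.items if key.reverse[i]]
    raw[rev] = 6.0 - raw[rev]
    raw[items.notna()] = items
    return raw


def apply_exclusion(
    scores: SubscaleScores, threshold: float = DEFAULT_EXCLUSION_THRESHOLD
) -> SubscaleScores:
    """Flag subjects missing strictly more than ``threshold`` of the form.

    A subject with exactly ``threshold * 39`` missing items is retained; the
    rule is strict inequality.
    """
    frac = scores.n_missing / N_ITEMS
    excluded = frac > threshold
    out_scores = scores.scores.copy()
    out_scores.loc[excluded] = np.nan
    return SubscaleScores(
        scores=out_scores,
        excluded=excluded,
        n_missing=scores.n_missing,
        threshold=threshold,
    )


def score_ffmq(
    items: pd.DataFrame,
    key: SubscaleKey | None = None,
    impute: bool = True,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> SubscaleScores:
    """Score an item-response table into five subscale totals.

    Parameters
    ----------
    items : DataFrame, subjects x 39 item columns, values in 1..5 or NaN
    key : subscale key; defaults to the shipped FFMQ-39 assignment
    impute : replace missing cells with the subject's subscale mean
    exclusion_threshold : maximum tolerated missing fraction of the form
    """
    key = key or default_key()
    items = _validate_items(items, key)
    n_missing = items.isna().sum(axis=1).astype(int)
    excluded = (n_missing / N_ITEMS) > exclusion_threshold

    work = items.copy()
    if impute and bool((items.isna().any(axis=1) & ~excluded).any()):
        kept = impute_subscale_mean(items.loc[~excluded], key)
        work.loc[~excluded] = kept
    scored = _reverse(work, key)

    totals = pd.DataFrame(
        {f: scored[list(key.items_for(f))].sum(axis=1, skipna=False) for f in FACETS},
        index=items.index,
    )
    result = SubscaleScores(
        scores=totals, excluded=pd.Series(False, index=items.index), n_missing=n_missing
    )
    return apply_exclusion(result, exclusion_threshold)


def standardize_facets(scores: SubscaleScores | pd.DataFrame) -> pd.DataFrame:
    """Column z-score subscale totals over included subjects (the PLS X block)."""
    table = scores.included if isinstance(scores, SubscaleScores) else scores
    if len(table) < 2:
        raise FFMQError("standardization needs at least 2 included subjects")
    sd = table.std(ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise FFMQError(f"zero-variance subscale column(s): {list(flat.index)}")
    return (table - table.mean()) / sd
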