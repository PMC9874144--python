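"""Per-subject annual cognitive change from long-format trajectories.

Cognitive testing is annual (RBANS index scores, standardized to mean 100,
SD 15); the analysis needs one change score per subject per index.  Two
estimators are provided:

* ``method="lmm"`` — a linear mixed-effects model per index,
  ``score ~ 1 + time`` with correlated random intercept and random slope per
  subject (REML).  The per-subject change score is the conditional (BLUP)
  slope: fixed slope + predicted random slope.  Single-visit subjects are
  retained and shrink to the fixed effect.
* ``method="ols"`` — independent per-subject least-squares slopes; requires
  >=2 distinct time points per subject (single-visit subjects are dropped
  with a logged count, or raise, per ``single_visit``).

BLUP slopes shrink toward the fixed effect, so their variance never exceeds
that of the OLS slopes on the same data; as residual variance goes to zero
the two coincide.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

__all__ = [
    "SlopeTable",
    "fit_trajectories",
    "align_slopes_to_facets",
    "align_by_subject",
    "TrajectoryError",
]

DEFAULT_INDEX_COLS = (
    "immediate_memory",
    "attention",
    "visuospatial",
    "language",
    "delayed_memory",
    "global_cognition",
)


class TrajectoryError(ValueError):
    """Inestimable slopes or a failed mixed-model fit."""


@dataclass
class SlopeTable:
    """Per-subject annual change estimates for each cognitive index."""

    slopes: pd.DataFrame  # subjects x indices, score units / year
    intercepts: pd.DataFrame  # subjects x indices
    n_visits: pd.Series  # visits per subject
    method: str

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat(
            {"slope": self.slopes, "intercept": self.intercepts}, axis=1
        )
        out.columns = [f"{col}_{kind}" for kind, col in out.columns]
        out["n_visits"] = self.n_visits
        return out


def _validate_long(
    long: pd.DataFrame, subject_col: str, time_col: str, index_cols: tuple[str, ...]
) -> pd.DataFrame:
    missing = [c for c in (subject_col, time_col, *index_cols) if c not in long.columns]
    if missing:
        raise TrajectoryError(f"long table lacks column(s): {missing}")
    if (long[time_col] < 0).any():
        raise TrajectoryError("times must be nonnegative (years from baseline)")
    vals = long[list(index_cols)].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise TrajectoryError("index scores must be finite")
    return long


def _ols_slopes(
    long: pd.DataFrame,
    subject_col: str,
    time_col: str,
    index_cols: tuple[str, ...],
    single_visit: str,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    g = long.groupby(subject_col)
    n_times = g[time_col].nunique()
    singles = n_times[n_times < 2].index
    if len(singles):
        if single_visit == "error":
            raise TrajectoryError(
                f"{len(singles)} single-visit subject(s) (<2 distinct time points) "
                f"under OLS: {list(singles[:5])}"
            )
        logger.info("dropping %d single-visit subject(s) for OLS slopes", len(singles))
        long = long[~long[subject_col].isin(singles)]
        g = long.groupby(subject_col)

    # closed-form least squares per (subject, index) via grouped sums
    t = long[time_col].to_numpy(dtype=float)
    work = pd.DataFrame({"subject": long[subject_col].to_numpy(), "t": t, "t2": t * t})
    for c in index_cols:
        y = long[c].to_numpy(dtype=float)
        work[f"y_{c}"] = y
        work[f"ty_{c}"] = t * y
    sums = work.groupby("subject").sum()
    cnt = work.groupby("subject").size()
    st, st2 = sums["t"], sums["t2"]
    denom = cnt * st2 - st**2
    slopes = {}
    inters = {}
    for c in index_cols:
        sy, sty = sums[f"y_{c}"], sums[f"ty_{c}"]
        slopes[c] = (cnt * sty - st * sy) / denom
        inters[c] = (sy - slopes[c] * st) / cnt
    return (
        pd.DataFrame(slopes),
        pd.DataFrame(inters),
        cnt.rename("n_visits"),
    )


def _lmm_slopes(
    long: pd.DataFrame,
    subject_col: str,
    time_col: str,
    index_cols: tuple[str, ...],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    n_times = long.groupby(subject_col)[time_col].nunique()
    if (n_times < 2).all():
        raise TrajectoryError("all subjects have a single visit; slopes inestimable")
    slopes = {}
    inters = {}
    data = long.rename(columns={subject_col: "_subject", time_col: "_time"})
    for c in index_cols:
        df = data[["_subject", "_time", c]].rename(columns={c: "_score"})
        model = smf.mixedlm("_score ~ _time", df, groups=df["_subject"], re_formula="~_time")
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                res = model.fit(reml=True)
            except (np.linalg.LinAlgError, ValueError):
                res = None
            if res is None or not np.isfinite(res.params).all():
                # fall back to independent random intercept/slope
                free = MixedLMParams.from_components(
                    fe_params=np.ones(2), cov_re=np.eye(2)
                )
                try:
                    res = model.fit(free=free, reml=True)
                except (np.linalg.LinAlgError, ValueError) as err:
                    raise TrajectoryError(
                        f"mixed model failed to converge for index {c!r}"
                    ) from err
        fe_int, fe_slope = float(res.fe_params.iloc[0]), float(res.fe_params.iloc[1])
        re = res.random_effects
        subj_ids = sorted(long[subject_col].unique())
        slopes[c] = pd.Series(
            {s: fe_slope + float(re[s].iloc[1]) if s in re else fe_slope for s in subj_ids}
        )
        inters[c] = pd.Series(
            {s: fe_int + float(re[s].iloc[0]) if s in re else fe_int for s in subj_ids}
        )
    cnt = long.groupby(subject_col).size().rename("n_visits")
    return pd.DataFrame(slopes), pd.DataFrame(inters), cnt


def fit_trajectories(
    long: pd.DataFrame,
    method: str = "lmm",
    subject_col: str = "subject",
    time_col: str = "time_years",
    index_cols: tuple[str, ...] | None = None,
    single_visit: str = "drop",
) -> SlopeTable:
    """Estimate per-subject annual change for each cognitive index.

    Parameters
    ----------
    long : long-format table (one row per subject-visit)
    method : "lmm" (BLUP slopes from a random-intercept/random-slope mixed
        model) or "ols" (independent per-subject least squares)
    single_visit : for OLS only — "drop" single-visit subjects with a logged
        count, or "error"
    """
    index_cols = tuple(index_cols) if index_cols is not None else DEFAULT_INDEX_COLS
    long = _validate_long(long, subject_col, time_col, index_cols)
    if method == "ols":
        slopes, inters, cnt = _ols_slopes(long, subject_col, time_col, index_cols, single_visit)
    elif method == "lmm":
        slopes, inters, cnt = _lmm_slopes(long, subject_col, time_col, index_cols)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'lmm' or 'ols'")
    slopes.index.name = subject_col
    inters.index.name = subject_col
    cnt.index.name = subject_col
    return SlopeTable(slopes=slopes, intercepts=inters, n_visits=cnt, method=method)


def align_by_subject(*frames: pd.DataFrame) -> tuple[pd.DataFrame, ...]:
    """Reindex any number of subject-indexed frames to their common ids.

    Rows are matched by subject identifier in a single sorted order; subjects
    absent from any frame are dropped with a logged count.  An empty
    intersection raises.
    """
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    if len(common) == 0:
        raise ValueError("no subjects shared by all tables")
    common = common.sort_values()
    for i, f in enumerate(frames):
        dropped = len(f) - len(common)
        if dropped:
            logger.info("alignment dropped %d subject(s) from table %d", dropped, i)
    return tuple(f.loc[common] for f in frames)


def align_slopes_to_facets(
    slopes: SlopeTable | pd.DataFrame, facets: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair the slope block with the facet block on shared subject ids."""
    slope_df = slopes.slopes if isinstance(slopes, SlopeTable) else slopes
    slope_df, facets = align_by_subject(slope_df, facets)
    return slope_df, facets
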