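"""Covariate-adjusted latent-score models and complementary analyses.

After a significant latent variable is found, the subject-level weighted
scores are carried into an ordinary least-squares model: the outcome latent
score is regressed on the behaviour latent score while controlling for age,
sex, education years, APOE-e4 carriage and the questionnaire-to-baseline
delay.  Both latent scores (and continuous covariates) are z-scored so the
reported coefficient for the behaviour score is a standardized beta; with no
covariates it equals the Pearson correlation of the two scores exactly.

Also here: the univariate facet-by-psychological-variable Pearson
correlation table, and the augmented PLS that appends standardized
psychological variables (personality, depression/anxiety/stress,
perseverative thinking) to the behaviour block.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pls import BehavioralPLS, BehavioralPLSResults, standardize_columns

logger = logging.getLogger(__name__)

__all__ = [
    "AdjustedModel",
    "adjusted_association",
    "facet_psych_correlations",
    "augmented_pls",
    "SingularityError",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "apoe4", "delta_days")


class SingularityError(ValueError):
    """Perfect collinearity among model predictors."""


@dataclass
class AdjustedModel:
    """OLS of the outcome latent score on the behaviour latent score."""

    beta: float
    tvalue: float
    pvalue: float
    n: int
    covariates: tuple[str, ...]
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "t": self.tvalue,
            "p": self.pvalue,
            "n": self.n,
            "covariates": list(self.covariates),
            "n_dropped": self.n_dropped,
        }


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if sd == 0:
        raise SingularityError(f"zero-variance variable {s.name!r}")
    return (s - s.mean()) / sd


def _is_binary(s: pd.Series) -> bool:
    vals = pd.unique(s.dropna())
    return len(vals) <= 2


def adjusted_association(
    ly: pd.Series | np.ndarray,
    lx: pd.Series | np.ndarray,
    covars: pd.DataFrame | None = None,
    covariates: tuple[str, ...] | None = None,
) -> AdjustedModel:
    """Standardized effect of the behaviour score controlling for covariates.

    ``ly`` and ``lx`` are z-scored; continuous covariates are z-scored too
    (binary columns left untouched), so ``beta`` is on the standardized
    scale.  Complete cases only; the dropped count is recorded.
    """
    ly = pd.Series(np.asarray(ly, dtype=float), name="ly") if not isinstance(ly, pd.Series) else ly.rename("ly")
    lx = pd.Series(np.asarray(lx, dtype=float), name="lx", index=ly.index) if not isinstance(lx, pd.Series) else lx.rename("lx")
    frame = pd.concat([ly, lx], axis=1)
    used: tuple[str, ...] = ()
    if covars is not None:
        used = tuple(covariates) if covariates is not None else tuple(
            c for c in DEFAULT_COVARIATES if c in covars.columns
        )
        missing = [c for c in used if c not in covars.columns]
        if missing:
            raise ValueError(f"covariate table lacks column(s): {missing}")
        frame = frame.join(covars[list(used)], how="inner")
    n_before = len(frame)
    frame = frame.dropna()
    n_dropped = n_before - len(frame)
    if n_dropped:
        logger.info("adjusted_association dropped %d incomplete case(s)", n_dropped)
    if len(frame) < len(used) + 3:
        raise ValueError("too few complete cases for the adjusted model")

    y = _zscore(frame["ly"])
    design = pd.DataFrame({"lx": _zscore(frame["lx"])})
    for c in used:
        col = frame[c].astype(float)
        design[c] = col if _is_binary(col) else _zscore(col)
    exog = sm.add_constant(design)
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        # identify an offending column by greedy removal, blaming a
        # covariate rather than the latent predictor where possible
        for c in list(design.columns)[::-1]:
            reduced = exog.drop(columns=[c])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise SingularityError(f"predictor {c!r} is perfectly collinear")
        raise SingularityError("perfectly collinear design matrix")
    res = sm.OLS(y, exog).fit()
    return AdjustedModel(
        beta=float(res.params["lx"]),
        tvalue=float(res.tvalues["lx"]),
        pvalue=float(res.pvalues["lx"]),
        n=len(frame),
        covariates=used,
        n_dropped=n_dropped,
    )


def facet_psych_correlations(
    facets: pd.DataFrame, psych: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise Pearson correlations between facets and psych variables.

    Returns a tidy table (facet, variable, r, p, n, undefined).  Pairs with
    zero variance are flagged ``undefined`` rather than raising.
    """
    rows = []
    for fcol in facets.columns:
        for pcol in psych.columns:
            pair = pd.concat(
                [facets[fcol].rename("a"), psych[pcol].rename("b")], axis=1
            ).dropna()
            a, b = pair["a"].to_numpy(float), pair["b"].to_numpy(float)
            undefined = len(pair) < 3 or a.std() == 0 or b.std() == 0
            if undefined:
                r = p = np.nan
            else:
                r, p = stats.pearsonr(a, b)
            rows.append((fcol, pcol, r, p, len(pair), undefined))
    return pd.DataFrame(
        rows, columns=["facet", "variable", "r", "p", "n", "undefined"]
    )


def augmented_pls(
    facets: pd.DataFrame,
    psych: pd.DataFrame,
    y: pd.DataFrame,
    **fit_kwargs,
) -> tuple[BehavioralPLSResults, dict]:
    """PLS with psychological variables appended to the behaviour block.

    ``psych`` columns are z-scored like the facets.  Returns the fitted
    results plus a label map distinguishing facets from the added variables.
    With an empty ``psych`` block this reduces exactly to the facet-only
    analysis.
    """
    dupes = set(facets.columns) & set(psych.columns)
    if dupes:
        raise ValueError(f"duplicated column names across blocks: {sorted(dupes)}")
    if len(psych.columns):
        psych = psych.loc[facets.index]
        psych_z = pd.DataFrame(
            standardize_columns(psych), index=psych.index, columns=psych.columns
        )
        x = pd.concat([facets, psych_z], axis=1)
        corr = np.corrcoef(x.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0)
        if np.nanmax(np.abs(corr)) > 0.999:
            warnings.warn(
                "near-perfect collinearity within the augmented behaviour block",
                stacklevel=2,
            )
    else:
        x = facets
    model = BehavioralPLS.from_dataframes(x, y)
    res = model.fit(**fit_kwargs)
    labels = {
        "facets": list(facets.columns),
        "psychological": list(psych.columns),
    }
    return res, labels
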