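"""Behavioral partial least squares (PLS) correlation.

Given an ``n x p`` behaviour block ``X`` and an ``n x q`` outcome block ``Y``
(both column-standardized), the method decomposes the cross-block correlation
matrix

    R = X'Y / (n - 1) = U S V'

into latent variables (LVs): each LV is a singular value ``s_i``, a behaviour
salience vector ``u_i`` and an outcome salience vector ``v_i``, chosen so the
projections ``X u_i`` and ``Y v_i`` maximally covary.  The share of
cross-block variance explained by LV ``i`` is ``s_i^2 / sum_j s_j^2``.

Inference is resampling based:

* **permutation test** — rows of ``Y`` are permuted (``X`` fixed), the
  decomposition recomputed, and each null singular value compared
  rank-for-rank to the observed one; p-values use the add-one rule
  ``(1 + #{null >= observed}) / (1 + n_perm)``.
* **bootstrap stability** — subjects are resampled with replacement (rows of
  ``X`` and ``Y`` jointly), each bootstrap decomposition is aligned to the
  original by an orthogonal Procrustes rotation of the behaviour saliences
  (axis flips/rotations in resamples are arbitrary), and the SD of the
  aligned saliences across resamples gives the bootstrap SE.  A behaviour
  facet is "stable" when ``u_j +/- se_multiplier * SE`` excludes zero; an
  outcome column when its bootstrap ratio ``|v_j / SE(v_j)|`` exceeds a
  pseudo-z threshold (1.96 by default).

The statsmodels-style entry point is :class:`BehavioralPLS` (a model built
from two blocks) whose :meth:`~BehavioralPLS.fit` returns
:class:`BehavioralPLSResults` with estimates, resampling inference, latent
scores and a ``summary()`` table.  The underlying steps are also exposed as
plain functions (:func:`crossblock_decompose`, :func:`permutation_test`,
:func:`bootstrap_stability`, :func:`latent_scores`).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BehavioralPLS",
    "BehavioralPLSResults",
    "CrossBlockDecomposition",
    "PermutationResult",
    "BootstrapResult",
    "LatentScores",
    "crossblock_decompose",
    "permutation_test",
    "bootstrap_stability",
    "latent_scores",
    "standardize_columns",
    "StandardizationError",
]

MEAN_TOL = 1e-6
SD_TOL = 1e-3


class StandardizationError(ValueError):
    """A block violated the standardized-columns contract."""


def standardize_columns(block: np.ndarray | pd.DataFrame, ddof: int = 1) -> np.ndarray:
    """Center each column and scale to unit sample SD."""
    arr = np.asarray(block, dtype=float)
    sd = arr.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise StandardizationError("cannot standardize a zero-variance column")
    return (arr - arr.mean(axis=0)) / sd


def _check_standardized(block: np.ndarray, name: str) -> None:
    mean = block.mean(axis=0)
    sd = block.std(axis=0, ddof=1)
    if np.any(np.abs(mean) > MEAN_TOL) or np.any(np.abs(sd - 1) > SD_TOL):
        j = int(np.argmax(np.maximum(np.abs(mean) / MEAN_TOL, np.abs(sd - 1) / SD_TOL)))
        raise StandardizationError(
            f"{name} column {j} is not standardized "
            f"(mean={mean[j]:.3g}, sd={sd[j]:.6g}); z-score columns first"
        )


@dataclass
class CrossBlockDecomposition:
    """SVD of the cross-block correlation matrix.

    ``behavior_saliences`` is p x k, ``outcome_saliences`` q x k, with
    orthonormal columns; ``pct_crossblock`` is ``100 * s_i^2 / sum s^2``.
    """

    singular_values: np.ndarray
    behavior_saliences: np.ndarray
    outcome_saliences: np.ndarray
    pct_crossblock: np.ndarray

    @property
    def n_lv(self) -> int:
        return len(self.singular_values)


@dataclass
class PermutationResult:
    pvalues: np.ndarray
    null_singular_values: np.ndarray  # n_perm x k
    n_perm: int
    seed: int | None


@dataclass
class BootstrapResult:
    behavior_se: np.ndarray  # p x k
    behavior_significant: np.ndarray  # p x k bool
    outcome_se: np.ndarray  # q x k
    outcome_bootstrap_ratios: np.ndarray  # q x k
    outcome_significant: np.ndarray  # q x k bool
    n_boot: int
    seed: int | None
    br_threshold: float
    se_multiplier: float
    n_redrawn: int = 0


@dataclass
class LatentScores:
    behavior_scores: np.ndarray  # n x k
    outcome_scores: np.ndarray  # n x k
    correlations: np.ndarray  # k


def _apply_sign_convention(
    u: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Flip each LV jointly so the largest-|u| element is positive."""
    u = u.copy()
    v = v.copy()
    for i in range(u.shape[1]):
        j = int(np.argmax(np.abs(u[:, i])))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            v[:, i] = -v[:, i]
    return u, v


def _crosscorr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return x.T @ y / (len(x) - 1)


def crossblock_decompose(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.DataFrame,
    check: bool = True,
) -> CrossBlockDecomposition:
    """SVD of ``R = X'Y/(n-1)`` with a deterministic sign convention.

    Both blocks must already be column-standardized; this is checked, not
    silently redone (``check=False`` skips the check for internal reuse on
    blocks standardized moments earlier).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or len(x) != len(y):
        raise ValueError("X and Y must be 2-D with equal row counts")
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("blocks must not contain missing values")
    if check:
        _check_standardized(x, "X")
        _check_standardized(y, "Y")
    r = _crosscorr(x, y)
    k = min(r.shape)
    if not r.any():
        warnings.warn("cross-correlation matrix is identically zero", stacklevel=2)
        return CrossBlockDecomposition(
            singular_values=np.zeros(k),
            behavior_saliences=np.eye(r.shape[0], k),
            outcome_saliences=np.eye(r.shape[1], k),
            pct_crossblock=np.full(k, np.nan),
        )
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    u, v = _apply_sign_convention(u, vt.T)
    pct = 100.0 * s**2 / np.sum(s**2)
    return CrossBlockDecomposition(
        singular_values=s,
        behavior_saliences=u,
        outcome_saliences=v,
        pct_crossblock=pct,
    )


def permutation_test(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    check: bool = True,
) -> PermutationResult:
    """Permutation null for the singular values, rank-for-rank.

    Rows of ``Y`` are permuted with ``X`` fixed, breaking any cross-block
    association while preserving each block's internal correlation structure.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = crossblock_decompose(x, y, check=check)
    rng = np.random.default_rng(seed)
    k = obs.n_lv
    null = np.empty((n_perm, k))
    for b in range(n_perm):
        perm = rng.permutation(len(y))
        null[b] = np.linalg.svd(_crosscorr(x, y[perm]), compute_uv=False)[:k]
    exceed = (null >= obs.singular_values[None, :]).sum(axis=0)
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationResult(
        pvalues=pvals, null_singular_values=null, n_perm=n_perm, seed=seed
    )


def _procrustes_rotation(u_ref: np.ndarray, u_boot: np.ndarray) -> np.ndarray:
    """Orthogonal Q minimizing ||U_boot Q - U_ref||_F."""
    w, _, zt = np.linalg.svd(u_boot.T @ u_ref)
    return w @ zt


def bootstrap_stability(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    br_threshold: float = 1.96,
    se_multiplier: float = 1.0,
    check: bool = True,
    max_redraws: int = 100,
    index_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> BootstrapResult:
    """Bootstrap SEs and bootstrap ratios for the saliences.

    Subjects are resampled with replacement jointly across blocks; each
    resample is re-standardized (its own correlation matrix is decomposed)
    and Procrustes-aligned to the original decomposition on the behaviour
    saliences, with the rotation applied to both salience sets.  Resamples
    with a zero-variance column are redrawn (counted in ``n_redrawn``).

    ``index_sampler(rng, n) -> indices`` overrides the resampling scheme
    (used by tests and available for stratified designs).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = crossblock_decompose(x, y, check=check)
    rng = np.random.default_rng(seed)
    n = len(x)
    draw = index_sampler or (lambda r, m: r.integers(0, m, m))

    u_stack = np.empty((n_boot,) + obs.behavior_saliences.shape)
    v_stack = np.empty((n_boot,) + obs.outcome_saliences.shape)
    n_redrawn = 0
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = draw(rng, n)
            xb, yb = x[idx], y[idx]
            if xb.std(axis=0).min() > 0 and yb.std(axis=0).min() > 0:
                break
            n_redrawn += 1
        else:
            raise RuntimeError(
                f"exceeded {max_redraws} redraws of a degenerate bootstrap resample"
            )
        ub_, sb, vbt = np.linalg.svd(
            _crosscorr(standardize_columns(xb), standardize_columns(yb)),
            full_matrices=False,
        )
        q = _procrustes_rotation(ub_, obs.behavior_saliences)
        u_stack[b] = ub_ @ q
        v_stack[b] = vbt.T @ q
    u_se = u_stack.std(axis=0, ddof=1)
    v_se = v_stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        br = np.where(v_se > 0, obs.outcome_saliences / v_se, np.inf * np.sign(obs.outcome_saliences))
    u = obs.behavior_saliences
    behavior_sig = (u - se_multiplier * u_se > 0) | (u + se_multiplier * u_se < 0)
    outcome_sig = np.abs(br) > br_threshold
    return BootstrapResult(
        behavior_se=u_se,
        behavior_significant=behavior_sig,
        outcome_se=v_se,
        outcome_bootstrap_ratios=br,
        outcome_significant=outcome_sig,
        n_boot=n_boot,
        seed=seed,
        br_threshold=br_threshold,
        se_multiplier=se_multiplier,
        n_redrawn=n_redrawn,
    )


def latent_scores(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.DataFrame,
    decomposition: CrossBlockDecomposition,
) -> LatentScores:
    """Subject-level weighted (latent) scores ``Lx = XU``, ``Ly = YV``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lx = x @ decomposition.behavior_saliences
    ly = y @ decomposition.outcome_saliences
    k = decomposition.n_lv
    corr = np.empty(k)
    for i in range(k):
        sx, sy = lx[:, i].std(ddof=1), ly[:, i].std(ddof=1)
        if sx == 0 or sy == 0:
            corr[i] = np.nan
        else:
            corr[i] = float(np.corrcoef(lx[:, i], ly[:, i])[0, 1])
    return LatentScores(behavior_scores=lx, outcome_scores=ly, correlations=corr)


class BehavioralPLS:
    """Behavioral PLS correlation model between two subject-aligned blocks.

    Parameters
    ----------
    x : behaviour block (n x p), e.g. z-scored mindfulness facets
    y : outcome block (n x q), e.g. cognitive slopes or regional SUVRs
    x_names, y_names : column labels (taken from DataFrames when omitted)
    standardize : z-score the blocks on construction (default).  With
        ``standardize=False`` the blocks must already satisfy the
        standardized-columns contract.

    Examples
    --------
    >>> model = BehavioralPLS(facets, slopes)
    >>> res = model.fit(n_perm=1000, n_boot=1000, seed=7)
    >>> print(res.summary())
    """

    def __init__(
        self,
        x,
        y,
        x_names: Sequence[str] | None = None,
        y_names: Sequence[str] | None = None,
        standardize: bool = True,
    ) -> None:
        if x_names is None and isinstance(x, pd.DataFrame):
            x_names = list(x.columns)
        if y_names is None and isinstance(y, pd.DataFrame):
            y_names = list(y.columns)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if standardize:
            x = standardize_columns(x)
            y = standardize_columns(y)
        else:
            _check_standardized(x, "X")
            _check_standardized(y, "Y")
        self.x = x
        self.y = y
        self.x_names = list(x_names) if x_names is not None else [f"x{j}" for j in range(x.shape[1])]
        self.y_names = list(y_names) if y_names is not None else [f"y{j}" for j in range(y.shape[1])]

    @classmethod
    def from_dataframes(cls, x: pd.DataFrame, y: pd.DataFrame, **kwargs) -> "BehavioralPLS":
        """Build from two DataFrames indexed by subject; rows are aligned by id."""
        common = x.index.intersection(y.index)
        if len(common) == 0:
            raise ValueError("no overlapping subjects between blocks")
        common = common.sort_values()
        return cls(x.loc[common], y.loc[common], **kwargs)

    def fit(
        self,
        n_perm: int = 1000,
        n_boot: int = 1000,
        seed: int | None = None,
        br_threshold: float = 1.96,
        se_multiplier: float = 1.0,
        alpha: float = 0.05,
    ) -> "BehavioralPLSResults":
        """Decompose and run permutation + bootstrap inference."""
        decomp = crossblock_decompose(self.x, self.y, check=False)
        ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
        perm_seed, boot_seed = (int(s) for s in ss.generate_state(2) % (2**31))
        perm = permutation_test(self.x, self.y, n_perm=n_perm, seed=perm_seed, check=False)
        boot = bootstrap_stability(
            self.x,
            self.y,
            n_boot=n_boot,
            seed=boot_seed,
            br_threshold=br_threshold,
            se_multiplier=se_multiplier,
            check=False,
        )
        scores = latent_scores(self.x, self.y, decomp)
        return BehavioralPLSResults(
            model=self,
            decomposition=decomp,
            permutation=perm,
            bootstrap=boot,
            scores=scores,
            alpha=alpha,
            seed=seed,
        )


@dataclass
class BehavioralPLSResults:
    """Fitted behavioral PLS correlation: estimates, inference, scores."""

    model: BehavioralPLS
    decomposition: CrossBlockDecomposition
    permutation: PermutationResult
    bootstrap: BootstrapResult
    scores: LatentScores
    alpha: float = 0.05
    seed: int | None = None

    # -- convenience accessors -------------------------------------------
    @property
    def singular_values(self) -> np.ndarray:
        return self.decomposition.singular_values

    @property
    def pct_crossblock(self) -> np.ndarray:
        return self.decomposition.pct_crossblock

    @property
    def pvalues(self) -> np.ndarray:
        return self.permutation.pvalues

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.pvalues < self.alpha))

    def behavior_table(self, lv: int = 0) -> pd.DataFrame:
        """Behaviour saliences, bootstrap SEs and stability flags for one LV."""
        d, b = self.decomposition, self.bootstrap
        return pd.DataFrame(
            {
                "salience": d.behavior_saliences[:, lv],
                "boot_se": b.behavior_se[:, lv],
                "significant": b.behavior_significant[:, lv],
            },
            index=pd.Index(self.model.x_names, name="variable"),
        )

    def outcome_table(self, lv: int = 0) -> pd.DataFrame:
        """Outcome saliences and bootstrap ratios for one LV."""
        d, b = self.decomposition, self.bootstrap
        return pd.DataFrame(
            {
                "salience": d.outcome_saliences[:, lv],
                "boot_se": b.outcome_se[:, lv],
                "bootstrap_ratio": b.outcome_bootstrap_ratios[:, lv],
                "significant": b.outcome_significant[:, lv],
            },
            index=pd.Index(self.model.y_names, name="variable"),
        )

    def lv_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "singular_value": self.singular_values,
                "pct_crossblock": self.pct_crossblock,
                "perm_p": self.pvalues,
                "latent_corr": self.scores.correlations,
            },
            index=pd.Index(range(1, self.decomposition.n_lv + 1), name="lv"),
        )

    def summary(self, max_outcome_rows: int = 20) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        lines = ["Behavioral PLS Correlation Results", "=" * 60]
        n, p = self.model.x.shape
        q = self.model.y.shape[1]
        lines.append(f"n subjects: {n}    behaviour vars: {p}    outcome vars: {q}")
        lines.append(
            f"n_perm: {self.permutation.n_perm}    n_boot: {self.bootstrap.n_boot}"
            f"    seed: {self.seed}"
        )
        lines.append("")
        lines.append(self.lv_table().to_string(float_format="%.4f"))
        for lv in range(self.decomposition.n_lv):
            if self.pvalues[lv] >= self.alpha:
                continue
            lines.append("")
            lines.append(f"-- LV{lv + 1} (p={self.pvalues[lv]:.4g}) " + "-" * 30)
            lines.append("behaviour saliences:")
            lines.append(self.behavior_table(lv).to_string(float_format="%.4f"))
            out = self.outcome_table(lv)
            lines.append("outcome bootstrap ratios:")
            if len(out) > max_outcome_rows:
                shown = out.reindex(
                    out["bootstrap_ratio"].abs().sort_values(ascending=False).index
                ).head(max_outcome_rows)
                lines.append(shown.to_string(float_format="%.4f"))
                lines.append(f"... ({len(out) - max_outcome_rows} more rows)")
            else:
                lines.append(out.to_string(float_format="%.4f"))
        return "\n".join(lines)

    def plot_saliences(self, lv: int = 0, ax=None):
        """Bar plot of behaviour saliences with bootstrap-SE error bars."""
        import matplotlib.pyplot as plt

        tab = self.behavior_table(lv)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        colors = ["tab:purple" if s else "0.7" for s in tab["significant"]]
        ax.bar(tab.index, tab["salience"], yerr=tab["boot_se"], color=colors, capsize=3)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel(f"LV{lv + 1} salience")
        ax.tick_params(axis="x", rotation=45)
        return ax
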