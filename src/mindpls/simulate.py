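"""Synthetic cohorts with the statistical structure the analysis assumes.

The real study data are available only on request, so every downstream stage
is exercised on generated cohorts that mimic an aging observational sample
with a family history of Alzheimer's dementia: a 39-item mindfulness
questionnaire, annual cognitive index scores over up to seven years of
follow-up, cross-sectional regional amyloid and tau SUVR tables for a PET
subsample, and a covariate table.

The cross-block dependence is driven by a single standard-normal latent
factor ``f`` per subject.  For a block with unit-norm planted salience ``a``
(length m) and effect size ``r`` in [0, 1), each standardized column is

    z_j = c_j * f + sqrt(1 - c_j^2) * eps_j,    c_j = sqrt(r) * a_j * sqrt(m)

so every column keeps exactly its configured marginal SD while the
cross-block correlation matrix between any two blocks is rank one and
proportional to the outer product of their planted saliences — the planted
salience *is* the population singular vector.  ``r`` is the share of a
column's variance carried by the factor when the salience is uniform; with
``r = 0`` blocks are mutually independent.  The loading constraint
``|c_j| <= 1`` is validated at configuration time.

Questionnaire items are derived from the target subscale totals by rounding
the total to the nearest attainable integer, splitting it evenly across the
subscale's items (remainder to the first items), and storing reverse-keyed
items as ``6 - value`` — so the scorer inverts the construction exactly.

The ``truth`` component (latent factor values, planted saliences, true
slopes, PET subject list) exists only for recovery tests; analysis modules
never read it.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ffmq
from .regions import default_region_set

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "inject_item_missingness"]


def _unit(vec) -> tuple[float, ...]:
    arr = np.asarray(vec, dtype=float)
    norm = float(np.linalg.norm(arr))
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("salience vector must be nonzero and finite")
    return tuple(arr / norm)


_DEF_BEHAVIOR_SALIENCE = (0.15, 0.45, 0.35, 0.65, 0.48)
_DEF_COGNITION_SALIENCE = (0.45, 0.55, 0.10, 0.15, 0.45, 0.52)

INDEX_COLS = (
    "immediate_memory",
    "attention",
    "visuospatial",
    "language",
    "delayed_memory",
    "global_cognition",
)

PSYCH_VARS = (
    "neuroticism",
    "extraversion",
    "openness",
    "agreeableness",
    "conscientiousness",
    "depression",
    "anxiety",
    "stress",
    "perseverative_thinking",
)


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults mirror the published sample description.

    Facet means/SDs, baseline index scores, demographic rates and the global
    amyloid / entorhinal tau SUVR moments follow the study's descriptive
    table; visit retention reproduces a median follow-up of ~5 years (range
    1-7).  ``latent_effect_r`` is the shared-factor effect size (see module
    docstring); per-block overrides default to it.
    """

    n_subjects: int = 261
    seed: int = 0

    # questionnaire
    facet_means: tuple[float, ...] = (27.55, 29.51, 31.01, 30.66, 23.11)
    facet_sds: tuple[float, ...] = (6.05, 6.04, 5.71, 5.51, 4.75)
    item_missing_rate: float = 0.01

    # longitudinal cognition
    index_baseline_means: tuple[float, ...] = (102.57, 107.02, 96.39, 103.75, 102.33, 102.82)
    index_baseline_sds: tuple[float, ...] = (11.39, 15.08, 13.63, 9.96, 9.09, 10.32)
    slope_means: tuple[float, ...] = (0.0,) * 6
    slope_sds: tuple[float, ...] = (1.0,) * 6
    residual_sd: float = 5.0
    max_followup_years: int = 7
    retention_year1: float = 0.985
    retention: float = 0.87

    # PET
    pet_fraction: float = 124 / 261
    abeta_suvr_mean: float = 1.34
    abeta_suvr_sd: float = 0.34
    tau_suvr_mean: float = 1.07
    tau_suvr_sd: float = 0.14

    # planted cross-block structure
    latent_effect_r: float = 0.25
    cognition_effect_r: float | None = None
    abeta_effect_r: float | None = None
    tau_effect_r: float | None = None
    planted_behavior_salience: tuple[float, ...] = _DEF_BEHAVIOR_SALIENCE
    cognition_salience: tuple[float, ...] = _DEF_COGNITION_SALIENCE
    abeta_salience: tuple[float, ...] | None = None  # default: uniform negative
    tau_salience: tuple[float, ...] | None = None

    # covariates
    age_mean: float = 67.27
    age_sd: float = 5.24
    female_prop: float = 0.713
    education_mean: float = 15.50
    education_sd: float = 3.46
    apoe4_prop: float = 0.387
    mci_prop: float = 0.046
    delta_days_mean: float = 1429.29
    delta_days_sd: float = 620.97
    age_confounding: float = 0.0  # correlation of age with the latent factor
    psych_loading: float = 0.0  # loading of psych variables on the factor

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("facet_sds", "index_baseline_sds", "slope_sds"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValueError(f"{name} must be positive")
        if self.abeta_suvr_sd <= 0 or self.tau_suvr_sd <= 0:
            raise ValueError("SUVR SDs must be positive")
        for name in ("latent_effect_r", "cognition_effect_r", "abeta_effect_r", "tau_effect_r"):
            r = getattr(self, name)
            if r is not None and not (0 <= r < 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0 <= self.item_missing_rate < 1):
            raise ValueError("item_missing_rate must lie in [0, 1)")
        if len(self.facet_means) != 5 or len(self.facet_sds) != 5:
            raise ValueError("facet_means/facet_sds must have length 5")
        if len(self.planted_behavior_salience) != 5:
            raise ValueError("planted_behavior_salience must have length 5")
        if len(self.cognition_salience) != len(INDEX_COLS):
            raise ValueError(f"cognition_salience must have length {len(INDEX_COLS)}")
        object.__setattr__(
            self, "planted_behavior_salience", _unit(self.planted_behavior_salience)
        )
        object.__setattr__(self, "cognition_salience", _unit(self.cognition_salience))
        n_ab = len(default_region_set("abeta").columns)
        n_tau = len(default_region_set("tau").columns)
        ab = self.abeta_salience if self.abeta_salience is not None else (-1.0,) * n_ab
        ta = self.tau_salience if self.tau_salience is not None else (-1.0,) * n_tau
        if len(ab) != n_ab:
            raise ValueError(f"abeta_salience must have length {n_ab}, got {len(ab)}")
        if len(ta) != n_tau:
            raise ValueError(f"tau_salience must have length {n_tau}, got {len(ta)}")
        object.__setattr__(self, "abeta_salience", _unit(ab))
        object.__setattr__(self, "tau_salience", _unit(ta))
        # loading constraint |c_j| <= 1 for every block
        for sal, r, label in (
            (self.planted_behavior_salience, self.latent_effect_r, "behaviour"),
            (self.cognition_salience, self._r("cognition"), "cognition"),
            (self.abeta_salience, self._r("abeta"), "abeta"),
            (self.tau_salience, self._r("tau"), "tau"),
        ):
            m = len(sal)
            cmax = np.sqrt(r * m) * np.max(np.abs(sal))
            if cmax > 1:
                raise ValueError(
                    f"{label} block loading exceeds 1 (={cmax:.3f}); reduce the "
                    "effect size or flatten the salience"
                )
        if not (0 < self.retention_year1 <= 1 and 0 < self.retention <= 1):
            raise ValueError("retention probabilities must lie in (0, 1]")
        if not (0 < self.pet_fraction <= 1):
            raise ValueError("pet_fraction must lie in (0, 1]")
        if abs(self.age_confounding) >= 1 or abs(self.psych_loading) >= 1:
            raise ValueError("age_confounding and psych_loading must lie in (-1, 1)")

    def _r(self, block: str) -> float:
        override = getattr(self, f"{block}_effect_r")
        return self.latent_effect_r if override is None else override

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticCohort:
    """Generated tables plus the planted ground truth (tests only)."""

    item_responses: pd.DataFrame
    cognition_long: pd.DataFrame
    abeta_suvr: pd.DataFrame
    tau_suvr: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict
    config: CohortConfig

    def write(self, outdir: str | Path) -> None:
        """Write the four tables as TSV plus a config/truth JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.item_responses.to_csv(outdir / "item_responses.tsv", sep="\t")
        self.cognition_long.to_csv(outdir / "cognition_long.tsv", sep="\t", index=False)
        self.abeta_suvr.to_csv(outdir / "abeta_suvr.tsv", sep="\t")
        self.tau_suvr.to_csv(outdir / "tau_suvr.tsv", sep="\t")
        self.covariates.to_csv(outdir / "covariates.tsv", sep="\t")
        sidecar = {
            "config": self.config.to_dict(),
            "truth": {
                k: (v.tolist() if isinstance(v, (np.ndarray, pd.Series)) else v)
                for k, v in self.truth.items()
                if k != "true_slopes"
            },
        }
        with open(outdir / "cohort_meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
        self.truth["true_slopes"].to_csv(outdir / "true_slopes.tsv", sep="\t")


def _latent_block(
    rng: np.random.Generator, f: np.ndarray, salience: tuple[float, ...], r: float
) -> np.ndarray:
    """Standardized block with rank-one cross-correlation to the factor."""
    m = len(salience)
    c = np.sqrt(r * m) * np.asarray(salience)
    eps = rng.standard_normal((len(f), m))
    return f[:, None] * c[None, :] + eps * np.sqrt(1.0 - c**2)[None, :]


def _items_from_totals(
    totals: pd.DataFrame, key: ffmq.SubscaleKey
) -> pd.DataFrame:
    """Distribute target subscale totals over items (graded rounding)."""
    n = len(totals)
    items = pd.DataFrame(
        np.empty((n, ffmq.N_ITEMS)), index=totals.index, columns=list(key.items)
    )
    for facet in ffmq.FACETS:
        cols = list(key.items_for(facet))
        m = len(cols)
        t = np.clip(np.rint(totals[facet].to_numpy()), m, 5 * m).astype(int)
        base, rem = np.divmod(t, m)
        block = np.tile(base[:, None], (1, m))
        block[np.arange(m)[None, :] < rem[:, None]] += 1
        items[cols] = block.astype(float)
    # store reverse-keyed items on the response scale
    rev = [i for i in key.items if key.reverse[i]]
    items[rev] = 6.0 - items[rev]
    return items


def inject_item_missingness(
    items: pd.DataFrame, rate: float, seed: int
) -> pd.DataFrame:
    """Blank each cell independently with probability ``rate``."""
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    out = items.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.shape) < rate
    out[mask] = np.nan
    return out


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort.

    The same config (including its seed) always yields byte-identical
    tables.  See the module docstring for the latent-factor model.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subjects = pd.Index([f"sub-{i:04d}" for i in range(1, n + 1)], name="subject")

    f = rng.standard_normal(n)

    # --- questionnaire items -------------------------------------------
    key = ffmq.default_key()
    facet_z = _latent_block(rng, f, config.planted_behavior_salience, config.latent_effect_r)
    totals = pd.DataFrame(
        np.asarray(config.facet_means) + np.asarray(config.facet_sds) * facet_z,
        index=subjects,
        columns=list(ffmq.FACETS),
    )
    items = _items_from_totals(totals, key)
    miss_seed = int(rng.integers(2**31))
    items = inject_item_missingness(items, config.item_missing_rate, miss_seed)

    # --- longitudinal cognition ----------------------------------------
    slope_z = _latent_block(rng, f, config.cognition_salience, config._r("cognition"))
    true_slopes = pd.DataFrame(
        np.asarray(config.slope_means) + np.asarray(config.slope_sds) * slope_z,
        index=subjects,
        columns=list(INDEX_COLS),
    )
    baselines = pd.DataFrame(
        np.asarray(config.index_baseline_means)
        + np.asarray(config.index_baseline_sds) * rng.standard_normal((n, len(INDEX_COLS))),
        index=subjects,
        columns=list(INDEX_COLS),
    )
    # visit schedule: baseline always; year-1 retention, then geometric dropout
    u = rng.random((n, config.max_followup_years))
    keep = np.ones((n, config.max_followup_years), dtype=bool)
    keep[:, 0] = u[:, 0] < config.retention_year1
    for t in range(1, config.max_followup_years):
        keep[:, t] = keep[:, t - 1] & (u[:, t] < config.retention)
    last_year = keep.sum(axis=1)  # 0..max_followup_years

    rows = []
    for i, subj in enumerate(subjects):
        times = np.arange(last_year[i] + 1, dtype=float)
        resid = rng.standard_normal((len(times), len(INDEX_COLS))) * config.residual_sd
        scores = (
            baselines.iloc[i].to_numpy()[None, :]
            + true_slopes.iloc[i].to_numpy()[None, :] * times[:, None]
            + resid
        )
        for j, t in enumerate(times):
            rows.append((subj, t, *scores[j]))
    cognition_long = pd.DataFrame(
        rows, columns=["subject", "time_years", *INDEX_COLS]
    )

    # --- PET ------------------------------------------------------------
    n_pet = max(2, int(round(config.pet_fraction * n)))
    pet_idx = np.sort(rng.choice(n, size=n_pet, replace=False))
    f_pet = f[pet_idx]
    pet_subjects = subjects[pet_idx]

    ab_set = default_region_set("abeta")
    tau_set = default_region_set("tau")
    ab_z = _latent_block(rng, f_pet, config.abeta_salience, config._r("abeta"))
    tau_z = _latent_block(rng, f_pet, config.tau_salience, config._r("tau"))
    abeta = pd.DataFrame(
        np.clip(config.abeta_suvr_mean + config.abeta_suvr_sd * ab_z, 0.01, None),
        index=pet_subjects,
        columns=list(ab_set.columns),
    )
    tau = pd.DataFrame(
        np.clip(config.tau_suvr_mean + config.tau_suvr_sd * tau_z, 0.01, None),
        index=pet_subjects,
        columns=list(tau_set.columns),
    )

    # --- covariates ------------------------------------------------------
    rho = config.age_confounding
    age = config.age_mean + config.age_sd * (
        rho * f + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    )
    lam = config.psych_loading
    psych = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, len(PSYCH_VARS)))
    covariates = pd.DataFrame(
        {
            "age": np.round(age, 2),
            "sex": (rng.random(n) < config.female_prop).astype(int),  # 1 = female
            "education": np.round(
                np.clip(config.education_mean + config.education_sd * rng.standard_normal(n), 6, 25),
                1,
            ),
            "apoe4": (rng.random(n) < config.apoe4_prop).astype(int),
            "delta_days": np.round(
                np.clip(
                    config.delta_days_mean + config.delta_days_sd * rng.standard_normal(n),
                    0,
                    None,
                )
            ),
            "mci_flag": (rng.random(n) < config.mci_prop).astype(int),
        },
        index=subjects,
    )
    covariates[list(PSYCH_VARS)] = np.round(psych, 6)

    truth = {
        "latent_factor": pd.Series(f, index=subjects, name="f"),
        "behavior_salience": list(config.planted_behavior_salience),
        "cognition_salience": list(config.cognition_salience),
        "abeta_salience": list(config.abeta_salience),
        "tau_salience": list(config.tau_salience),
        "pet_subjects": list(pet_subjects),
        "true_slopes": true_slopes,
    }
    return SyntheticCohort(
        item_responses=items,
        cognition_long=cognition_long,
        abeta_suvr=abeta,
        tau_suvr=tau,
        covariates=covariates,
        truth=truth,
        config=config,
    )
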