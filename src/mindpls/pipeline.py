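"""End-to-end study pipeline: three PLS analyses from one configuration.

``run_all`` executes the full chain — questionnaire scoring, slope
extraction, region validation, one behavioral PLS per outcome block
(longitudinal cognition, amyloid, tau), latent-score extraction and the
covariate-adjusted model — on either real input tables or a generated
synthetic cohort, with an optional sensitivity re-run excluding subjects who
developed mild cognitive impairment.  Everything is a pure function of
(inputs, config, seeds); the run manifest records seeds, library versions
and row counts at each stage.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, adjust, ffmq, regions, trajectories
from .pls import BehavioralPLS, BehavioralPLSResults
from .simulate import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "ReportBundle", "run_all", "subgroup_filter", "load_tables"]

ANALYSES = ("cognition", "abeta", "tau")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass(frozen=True)
class AnalysisConfig:
    """One config drives the whole study.

    Provide either ``input_dir`` (TSV tables as written by
    :meth:`mindpls.simulate.SyntheticCohort.write`) or ``synthetic`` (a
    :class:`CohortConfig`), not both.
    """

    input_dir: str | None = None
    synthetic: CohortConfig | None = None
    n_perm: int = 1000
    n_boot: int = 1000
    seed: int = 0
    alpha: float = 0.05
    br_threshold: float = 1.96
    se_multiplier: float = 1.0
    slope_method: str = "lmm"
    exclude_mci: bool = False
    pet_subsample_only: bool = False
    exclusion_threshold: float = 0.10
    report_all_lvs: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_dir or synthetic config")


@dataclass
class AnalysisReport:
    """One outcome block's results."""

    name: str
    pls: BehavioralPLSResults
    adjusted: adjust.AdjustedModel
    n_subjects: int

    def to_dict(self) -> dict:
        res = self.pls
        return {
            "name": self.name,
            "n_subjects": self.n_subjects,
            "singular_values": res.singular_values.tolist(),
            "pct_crossblock": res.pct_crossblock.tolist(),
            "perm_p": res.pvalues.tolist(),
            "latent_correlations": res.scores.correlations.tolist(),
            "n_significant_lvs": res.n_significant,
            "adjusted_model": self.adjusted.to_dict(),
        }


@dataclass
class ReportBundle:
    """Primary analyses (plus the optional MCI-excluded sensitivity run)."""

    analyses: dict
    manifest: dict
    sensitivity: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "manifest": self.manifest,
            "analyses": {k: v.to_dict() for k, v in self.analyses.items()},
        }
        if self.sensitivity is not None:
            out["sensitivity_mci_excluded"] = {
                k: v.to_dict() for k, v in self.sensitivity.items()
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        for name, rep in self.analyses.items():
            rep.pls.behavior_table(0).to_csv(outdir / f"{name}_behavior_lv1.tsv", sep="\t")
            rep.pls.outcome_table(0).to_csv(outdir / f"{name}_outcome_lv1.tsv", sep="\t")


def load_tables(input_dir: str | Path) -> dict:
    """Read the four study tables from TSV files in a directory."""
    d = Path(input_dir)
    return {
        "items": pd.read_csv(d / "item_responses.tsv", sep="\t", index_col="subject"),
        "cognition": pd.read_csv(d / "cognition_long.tsv", sep="\t"),
        "abeta": pd.read_csv(d / "abeta_suvr.tsv", sep="\t", index_col="subject"),
        "tau": pd.read_csv(d / "tau_suvr.tsv", sep="\t", index_col="subject"),
        "covariates": pd.read_csv(d / "covariates.tsv", sep="\t", index_col="subject"),
    }


def subgroup_filter(tables: dict, flag_column: str, exclude_value=1) -> dict:
    """Remove flagged subjects consistently from every table.

    The flag lives in the covariate table; rows of all tables belonging to
    flagged subjects are dropped.  Emptying the cohort raises.
    """
    cov = tables["covariates"]
    if flag_column not in cov.columns:
        raise PipelineError(f"subgroup_filter: flag column {flag_column!r} not found")
    drop_ids = set(cov.index[cov[flag_column] == exclude_value])
    keep_ids = set(cov.index) - drop_ids
    if not keep_ids:
        raise PipelineError(f"subgroup_filter on {flag_column!r} empties the cohort")
    logger.info("subgroup_filter %s: dropping %d of %d subjects", flag_column, len(drop_ids), len(cov))
    out = {}
    for name, tab in tables.items():
        if name == "cognition":
            out[name] = tab[~tab["subject"].isin(drop_ids)].reset_index(drop=True)
        else:
            out[name] = tab.loc[[i for i in tab.index if i not in drop_ids]]
    return out


def _analysis_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    vals = ss.generate_state(len(ANALYSES)) % (2**31)
    return {name: int(v) for name, v in zip(ANALYSES, vals)}


def _run_analyses(tables: dict, config: AnalysisConfig) -> dict:
    # stage: questionnaire scoring
    try:
        scores = ffmq.score_ffmq(
            tables["items"], exclusion_threshold=config.exclusion_threshold
        )
        facets = ffmq.standardize_facets(scores)
    except Exception as err:
        raise PipelineError(f"ffmq scoring stage failed: {err}") from err

    # stage: slope extraction
    try:
        slopes = trajectories.fit_trajectories(
            tables["cognition"], method=config.slope_method
        )
    except Exception as err:
        raise PipelineError(f"trajectory stage failed: {err}") from err

    # stage: region validation
    outcome_blocks = {"cognition": slopes.slopes}
    for tracer in ("abeta", "tau"):
        try:
            outcome_blocks[tracer] = regions.validate_suvr_table(
                tables[tracer], regions.default_region_set(tracer)
            )
        except Exception as err:
            raise PipelineError(f"region validation failed for {tracer}: {err}") from err

    seeds = _analysis_seeds(config.seed)
    covars = tables["covariates"]
    reports = {}
    for name in ANALYSES:
        y_block = outcome_blocks[name]
        x_al, y_al = trajectories.align_by_subject(facets, y_block)
        model = BehavioralPLS.from_dataframes(x_al, y_al)
        res = model.fit(
            n_perm=config.n_perm,
            n_boot=config.n_boot,
            seed=seeds[name],
            br_threshold=config.br_threshold,
            se_multiplier=config.se_multiplier,
            alpha=config.alpha,
        )
        # adjusted model on LV1 weighted scores (the dominant LV)
        idx = x_al.index
        delta = covars.loc[idx]
        adj = adjust.adjusted_association(
            pd.Series(res.scores.outcome_scores[:, 0], index=idx),
            pd.Series(res.scores.behavior_scores[:, 0], index=idx),
            covars=delta,
        )
        reports[name] = AnalysisReport(
            name=name, pls=res, adjusted=adj, n_subjects=len(idx)
        )
    return reports


def run_all(config: AnalysisConfig) -> ReportBundle:
    """Run the full study: scoring, slopes, three PLS analyses, adjustment."""
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        tables = {
            "items": cohort.item_responses,
            "cognition": cohort.cognition_long,
            "abeta": cohort.abeta_suvr,
            "tau": cohort.tau_suvr,
            "covariates": cohort.covariates,
        }
    else:
        tables = load_tables(config.input_dir)

    if config.pet_subsample_only:
        pet_ids = set(tables["abeta"].index)
        keep = [i for i in tables["covariates"].index if i in pet_ids]
        tables = {
            name: (
                tab[tab["subject"].isin(keep)].reset_index(drop=True)
                if name == "cognition"
                else tab.loc[[i for i in tab.index if i in keep]]
            )
            for name, tab in tables.items()
        }

    analyses = _run_analyses(tables, config)
    sensitivity = None
    if config.exclude_mci:
        filtered = subgroup_filter(tables, "mci_flag", 1)
        sensitivity = _run_analyses(filtered, config)

    import scipy
    import statsmodels

    manifest = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "seed": config.seed,
        "analysis_seeds": _analysis_seeds(config.seed),
        "settings": {
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "alpha": config.alpha,
            "br_threshold": config.br_threshold,
            "se_multiplier": config.se_multiplier,
            "slope_method": config.slope_method,
            "exclusion_threshold": config.exclusion_threshold,
        },
        "n_subjects": {name: rep.n_subjects for name, rep in analyses.items()},
        "synthetic": config.synthetic.to_dict() if config.synthetic else None,
        "input_dir": config.input_dir,
    }
    bundle = ReportBundle(analyses=analyses, manifest=manifest, sensitivity=sensitivity)
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
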