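"""End-to-end analysis pipeline and sensitivity variants.

Orchestrates: cohort exclusions -> PRS construction from summary statistics
(filter, clump, score, threshold ladder) -> mixed correlation matrix of
ordinal items and covariates -> correlated-factors and general-factor SEM
fits with family-clustered sandwich errors -> nested comparison ->
psychometric summaries (loading tables, beta/R^2 tables, explained common
variance).  The sensitivity suite re-runs the analysis excluding ADHD
cases, keeping one twin per MZ pair, stratifying by sex, and sweeping the
PRS p-value threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics
from .polycor import mixed_correlation_matrix
from .prs import (
    DEFAULT_THRESHOLDS,
    GenotypePanel,
    SummaryStatRecord,
    clump,
    filter_variants,
    score_profiles,
    standardize_effects,
)
from .sem import FitResult, NestedTestResult, build_model, fit_dwls, nested_difference_test
from .simulate import EXCLUSION_FLAGS

__all__ = [
    "AnalysisConfig",
    "ResultsBundle",
    "apply_exclusions",
    "run_analysis",
    "sensitivity_suite",
]

#: Domain labels for the generator's reduced scales, merged over the
#: questionnaire defaults so pipeline outputs can always be summarized.
PIPELINE_DOMAINS = {**metrics.DEFAULT_DOMAINS,
                    "EXT": "externalizing", "INT": "internalizing"}


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run (YAML-serializable)."""

    factor_items: dict[str, list[str]]
    covariates: list[str] = field(
        default_factory=lambda: ["prs", "sex", "age"] + [f"pc{i+1}" for i in range(6)]
    )
    prs_thresholds: list[float] = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    main_threshold: float = 0.5
    maf_min: float = 0.05
    info_min: float = 0.8
    clump_r2: float = 0.1
    clump_window_kb: float = 1000.0
    min_pair_n: int = 50
    adhd_symptom_cutoff: int = 8
    max_missing_scale_fraction: float = 0.2
    use_true_score: bool = False  # regress on the generating score (recovery tests)
    nested_method: str = "scaled"
    subsample: str = "synthetic"
    seed: int = 0

    def validate(self, cohort: pd.DataFrame) -> None:
        missing = [it for its in self.factor_items.values() for it in its
                   if it not in cohort.columns]
        if missing:
            raise ValueError(f"items not present in cohort: {missing}")
        cov_needed = [c for c in self.covariates if c != "prs"]
        missing_cov = [c for c in cov_needed if c not in cohort.columns]
        if missing_cov:
            raise ValueError(f"covariates not present in cohort: {missing_cov}")

    @property
    def items(self) -> list[str]:
        return [it for its in self.factor_items.values() for it in its]

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove children with any medical exclusion flag.

    Returns the filtered cohort and a per-reason tally; a child with
    several flags is removed once but counted under each reason.
    """
    flags = [f for f in EXCLUSION_FLAGS if f in cohort.columns]
    tally = {f: int(cohort[f].sum()) for f in flags}
    if flags:
        any_flag = cohort[flags].any(axis=1)
        tally["total_removed"] = int(any_flag.sum())
        cohort = cohort.loc[~any_flag]
    else:
        tally["total_removed"] = 0
    return cohort.reset_index(drop=True), tally


def _drop_sparse_responders(cohort: pd.DataFrame, config: AnalysisConfig
                            ) -> pd.DataFrame:
    """Drop children missing more than the allowed share of a scale's items."""
    keep = np.ones(len(cohort), dtype=bool)
    for factor, its in config.factor_items.items():
        frac = cohort[its].isna().mean(axis=1)
        keep &= (frac <= config.max_missing_scale_fraction).to_numpy()
    return cohort.loc[keep].reset_index(drop=True)


def build_prs(panel: GenotypePanel, sumstats: Sequence[SummaryStatRecord],
              config: AnalysisConfig):
    """Filter, clump and score: the PRS block of the pipeline."""
    kept, tally = filter_variants(sumstats, config.maf_min, config.info_min)
    index_ids, report = clump(kept, panel, config.clump_r2, config.clump_window_kb)
    kept_by_id = {r.variant_id: r for r in kept}
    effects = standardize_effects([kept_by_id[v] for v in index_ids])
    prs = score_profiles(panel, effects, sumstats, config.prs_thresholds)
    return prs, {"filter_tally": tally, "n_index_variants": len(index_ids),
                 "clump_report": report}


@dataclass
class ResultsBundle:
    """Everything one analysis run produces."""

    config: AnalysisConfig
    n_children: int
    exclusion_tally: dict
    prs_info: dict
    fit_correlated: FitResult
    fit_general: FitResult
    nested: NestedTestResult
    loading_table: pd.DataFrame
    beta_table: pd.DataFrame
    ecv: float
    loading_summary: pd.DataFrame

    def to_dir(self, out_dir: str | os.PathLike) -> None:
        out = os.fspath(out_dir)
        os.makedirs(out, exist_ok=True)
        self.loading_table.to_csv(os.path.join(out, "loadings.tsv"),
                                  sep="\t", index=False)
        self.beta_table.to_csv(os.path.join(out, "betas.tsv"), sep="\t", index=False)
        self.loading_summary.to_csv(os.path.join(out, "loading_summary.tsv"), sep="\t")
        meta = {
            "schema_version": 1,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "subsample": self.config.subsample,
            "n_children": self.n_children,
            "exclusions": self.exclusion_tally,
            "n_index_variants": self.prs_info.get("n_index_variants"),
            "ecv_percent": self.ecv,
            "fit": {
                "correlated": _fit_summary(self.fit_correlated),
                "general": _fit_summary(self.fit_general),
            },
            "nested_test": {
                "delta_chi2": self.nested.delta_chi2,
                "delta_df": self.nested.delta_df,
                "p_value": self.nested.p_value,
                "method": self.nested.method,
            },
        }
        with open(os.path.join(out, "results.json"), "w") as fh:
            json.dump(meta, fh, indent=1)


def _fit_summary(fit: FitResult) -> dict:
    return {
        "chi2": fit.chi2, "df": fit.df, "cfi": fit.cfi,
        "rmsea": fit.rmsea, "rmsea_ci90": list(fit.rmsea_ci),
        "converged": fit.converged, "discrepancy": fit.discrepancy,
    }


def run_analysis(
    cohort: pd.DataFrame,
    panel: GenotypePanel | None,
    sumstats: Sequence[SummaryStatRecord] | None,
    config: AnalysisConfig,
    out_dir: str | os.PathLike | None = None,
) -> ResultsBundle:
    """Full analysis of one subsample: PRS, both SEM fits, summaries.

    With ``use_true_score`` the generating polygenic score column of a
    synthetic cohort replaces the constructed PRS (parameter-recovery
    mode); otherwise ``panel`` and ``sumstats`` are required.
    """
    config.validate(cohort)
    cohort, tally = apply_exclusions(cohort)
    cohort = _drop_sparse_responders(cohort, config)

    prs_info: dict = {}
    if config.use_true_score:
        if "prs_true" not in cohort.columns:
            raise ValueError("cohort has no 'prs_true' column for recovery mode")
        cohort = cohort.assign(prs=cohort["prs_true"])
    else:
        if panel is None or sumstats is None:
            raise ValueError("panel and sumstats are required unless use_true_score")
        prs, prs_info = build_prs(panel, sumstats, config)
        scores = prs.scores(config.main_threshold).rename("prs")
        cohort = cohort.merge(scores, left_on="child_id", right_index=True,
                              how="inner")
        prs_info["prs_result"] = prs
    if cohort["prs"].isna().any():
        cohort = cohort.loc[cohort["prs"].notna()].reset_index(drop=True)

    return _fit_bundle(cohort, config, tally, prs_info)


def _fit_bundle(cohort: pd.DataFrame, config: AnalysisConfig, tally: dict,
                prs_info: dict) -> ResultsBundle:
    items = config.items
    covs = list(config.covariates)
    moments = mixed_correlation_matrix(
        cohort, ordinal=items, continuous=covs, min_pair_n=config.min_pair_n
    )
    clusters = cohort["family_id"].to_numpy()
    spec_cf = build_model(config.factor_items, general=False, covariates=covs)
    spec_gf = build_model(config.factor_items, general=True, covariates=covs)
    fit_cf = fit_dwls(spec_cf, moments, clusters=clusters)
    fit_gf = fit_dwls(spec_gf, moments, clusters=clusters)
    nested = nested_difference_test(fit_cf, fit_gf, method=config.nested_method,
                                    seed=config.seed)

    # Table-2-style loadings: specific loadings from both models + general
    lt_gf = fit_gf.loading_table(PIPELINE_DOMAINS)
    lt_cf = fit_cf.loadings.rename(columns={"specific": "specific_correlated"})
    loading_table = lt_gf.merge(lt_cf[["item", "specific_correlated"]], on="item")

    # Table-3-style regressions from both models
    b_cf = fit_cf.betas.assign(model="correlated_factors")
    b_gf = fit_gf.betas.assign(model="general_factor")
    beta_table = pd.concat([b_cf, b_gf], ignore_index=True)

    ecv_val = metrics.ecv(lt_gf)
    summary = metrics.loading_summary(lt_gf)

    return ResultsBundle(
        config=config, n_children=len(cohort), exclusion_tally=tally,
        prs_info=prs_info, fit_correlated=fit_cf, fit_general=fit_gf,
        nested=nested, loading_table=loading_table, beta_table=beta_table,
        ecv=ecv_val, loading_summary=summary,
    )


# ----------------------------------------------------------------------
# sensitivity analyses


def _drop_adhd_cases(cohort: pd.DataFrame, cutoff: int) -> pd.DataFrame:
    sym = np.zeros(len(cohort), dtype=bool)
    for dim in ("IA", "HI"):
        col = f"symptoms_{dim}"
        if col in cohort.columns:
            sym |= (cohort[col] >= cutoff).to_numpy()
    diag = cohort["adhd_diagnosis"].to_numpy(dtype=bool) \
        if "adhd_diagnosis" in cohort.columns else np.zeros(len(cohort), bool)
    return cohort.loc[~(sym | diag)].reset_index(drop=True)


def _drop_one_mz_twin(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Seeded uniform choice of which MZ co-twin to keep."""
    rng = np.random.default_rng(seed)
    drop_idx = []
    mz = cohort.loc[cohort["zygosity"] == "MZ"]
    for fam, grp in mz.groupby("family_id", sort=True):
        if len(grp) > 1:
            drop_idx.append(rng.choice(grp.index.to_numpy()))
    return cohort.drop(index=drop_idx).reset_index(drop=True)


def sensitivity_suite(
    cohort: pd.DataFrame,
    panel: GenotypePanel | None,
    sumstats: Sequence[SummaryStatRecord] | None,
    config: AnalysisConfig,
) -> dict:
    """The four robustness variants of the main analysis.

    1. ``adhd_excluded`` -- drop children with a diagnosis flag or at least
       the cutoff number of DSM symptoms on either ADHD dimension;
    2. ``one_mz_per_pair`` -- randomly (seeded) keep one twin per MZ pair;
    3. ``sex_stratified`` -- separate refits per sex (sex dropped from the
       covariates within strata);
    4. ``threshold_sweep`` -- PRS-path estimates at every configured
       p-value threshold.
    A variant that would empty a required group is skipped with a warning.
    """
    results: dict = {}

    variant = _drop_adhd_cases(cohort, config.adhd_symptom_cutoff)
    results["adhd_excluded"] = run_analysis(variant, panel, sumstats, config)

    variant = _drop_one_mz_twin(cohort, config.seed)
    results["one_mz_per_pair"] = run_analysis(variant, panel, sumstats, config)

    strata = {}
    for sex_val, label in ((0, "sex0"), (1, "sex1")):
        sub = cohort.loc[cohort["sex"] == sex_val]
        if len(sub) < 50:
            warnings.warn(f"sex stratum {label} too small; skipped", RuntimeWarning)
            continue
        cfg = dataclasses.replace(
            config, covariates=[c for c in config.covariates if c != "sex"]
        )
        strata[label] = run_analysis(sub.reset_index(drop=True), panel, sumstats, cfg)
    results["sex_stratified"] = strata

    sweep_rows = []
    if config.use_true_score:
        warnings.warn("threshold sweep skipped: run uses the true score",
                      RuntimeWarning)
    else:
        base_cohort, _ = apply_exclusions(cohort)
        base_cohort = _drop_sparse_responders(base_cohort, config)
        prs, _ = build_prs(panel, sumstats, config)
        for thr in sorted(config.prs_thresholds):
            scores = prs.scores(thr).rename("prs")
            merged = base_cohort.merge(scores, left_on="child_id",
                                       right_index=True, how="inner")
            merged = merged.loc[merged["prs"].notna()].reset_index(drop=True)
            if merged["prs"].std() == 0 or len(merged) < 50:
                warnings.warn(f"threshold {thr}: no usable score; skipped",
                              RuntimeWarning)
                continue
            bundle = _fit_bundle(merged, config, {}, {})
            b = bundle.beta_table
            b = b.loc[(b["covariate"] == "prs")
                      & (b["model"] == "general_factor")].copy()
            b["p_threshold"] = thr
            sweep_rows.append(b)
    results["threshold_sweep"] = (
        pd.concat(sweep_rows, ignore_index=True) if sweep_rows else pd.DataFrame()
    )
    return results
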