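"""Synthetic discovery GWAS and target twin cohort.

The generator mirrors the statistical structure the downstream analysis
assumes, so that parameter recovery is a well-posed test:

* a discovery GWAS of an ADHD-like trait is emulated at the summary-statistic
  level (per-variant z-scores with sampling noise at a stated effective N);
* a target cohort of twin pairs is drawn by Mendelian transmission from
  simulated parents -- monozygotic (MZ) pairs share genotypes exactly,
  dizygotic (DZ) pairs share each parental allele with probability 1/2;
* a true polygenic score loads on a general psychopathology factor (effect
  ``gamma_gp``) and on a specific hyperactivity/impulsivity factor
  (``gamma_hi``); items are graded 0/1/2 responses obtained by thresholding
  continuous latent responses generated from a bifactor model;
* a family-shared disturbance component (share ``family_env_share`` of each
  factor disturbance) makes twins cluster, which is what the cluster-robust
  standard errors must absorb.

Every generator draws from one :class:`numpy.random.Generator` seeded from
``SimulationConfig.seed``, so a fixed config is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .prs import GenotypePanel, SummaryStatRecord

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "default_loading_plan",
    "simulate_discovery_sumstats",
    "simulate_twin_genotypes",
    "simulate_item_responses",
    "simulate_cohort",
    "family_table",
]

EXCLUSION_FLAGS = ("excl_cerebral_palsy", "excl_down_syndrome",
                   "excl_brain_injury", "excl_chromosomal")


def default_loading_plan() -> dict[str, list[tuple[float, float]]]:
    """Reduced four-factor design with Table-2-like loading magnitudes.

    Four specific factors x four items: inattention-like items load strongly
    on the general factor, hyperactivity/impulsivity and externalizing
    moderately, internalizing weakly -- echoing the typical ordering of
    general-factor loadings for these domains.
    Each entry is (general loading, specific loading).
    """
    return {
        "IA": [(0.85, 0.25), (0.80, 0.30), (0.75, 0.35), (0.70, 0.40)],
        "HI": [(0.65, 0.50), (0.60, 0.55), (0.60, 0.50), (0.55, 0.50)],
        "EXT": [(0.50, 0.60), (0.50, 0.55), (0.45, 0.60), (0.55, 0.50)],
        "INT": [(0.40, 0.65), (0.35, 0.60), (0.30, 0.65), (0.40, 0.60)],
    }


def _default_covariate_effects() -> dict[str, dict[str, float]]:
    # Small realistic covariate effects; PCs carry no phenotypic effect by
    # default (they exist to be adjusted for).
    return {
        "sex": {"GP": 0.10, "IA": 0.10, "HI": 0.15, "EXT": 0.10, "INT": -0.05},
        "age": {"GP": 0.05, "INT": 0.05},
    }


@dataclass
class SimulationConfig:
    """Generating parameters for the discovery GWAS and the twin cohort."""

    n_variants: int = 2000
    causal_fraction: float = 0.2
    heritability_target: float = 0.25
    n_eff_discovery: float = 55_000.0
    n_families: int = 2000
    mz_fraction: float = 1.0 / 3.0
    gamma_gp: float = 0.10
    gamma_hi: float = 0.07
    loading_plan: dict[str, list[tuple[float, float]]] = field(
        default_factory=default_loading_plan
    )
    threshold_plan: dict[str, tuple[float, float]] | None = None
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_covariate_effects
    )
    n_pcs: int = 6
    specific_corr: float = 0.2  # cross-factor disturbance correlation (same child)
    family_env_share: float = 0.2  # family-shared share of each factor disturbance
    artifact_fraction: float = 0.06  # sumstats flagged indel/ambiguous/low-INFO
    exclusion_prevalence: float = 0.01
    adhd_icd_prevalence: float = 0.03
    adhd_symptom_cutoff: int = 8
    missing_rate: float = 0.0
    ld_block_size: int = 1  # >1 turns on block-exchangeable LD
    ld_block_r: float = 0.0
    seed: int = 0

    # -- derived -------------------------------------------------------
    @property
    def items(self) -> list[str]:
        return [f"{f}{k + 1}" for f, plan in self.loading_plan.items()
                for k in range(len(plan))]

    @property
    def factors(self) -> list[str]:
        return list(self.loading_plan)

    @property
    def factor_of_item(self) -> dict[str, str]:
        return {f"{f}{k + 1}": f for f, plan in self.loading_plan.items()
                for k in range(len(plan))}

    @property
    def n_mz(self) -> int:
        return int(round(self.mz_fraction * self.n_families))

    def thresholds_for(self, item: str) -> tuple[float, float]:
        if self.threshold_plan and item in self.threshold_plan:
            return self.threshold_plan[item]
        return (0.6, 1.5)

    def covariate_names(self) -> list[str]:
        return ["sex", "age"] + [f"pc{i + 1}" for i in range(self.n_pcs)]

    def validate(self) -> None:
        for name in ("causal_fraction", "heritability_target", "mz_fraction",
                     "specific_corr", "family_env_share", "artifact_fraction",
                     "exclusion_prevalence", "adhd_icd_prevalence",
                     "missing_rate", "ld_block_r"):
            val = getattr(self, name)
            if not np.isfinite(val) or not (0.0 <= val <= 1.0):
                raise ValueError(f"config field {name!r} must be in [0,1], got {val!r}")
        for name in ("n_eff_discovery", "gamma_gp", "gamma_hi"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"config field {name!r} must be finite")
        if self.n_variants < 1 or self.n_families < 1:
            raise ValueError("n_variants and n_families must be >= 1")
        for item in self.items:
            lam_g, lam_s = self._item_loadings(item)
            if lam_g * lam_g + lam_s * lam_s > 1.0 + 1e-12:
                raise ValueError(
                    f"item {item!r}: communality lambda_g^2 + lambda_s^2 > 1"
                )
            t1, t2 = self.thresholds_for(item)
            if not (np.isfinite(t1) and np.isfinite(t2) and t1 < t2):
                raise ValueError(f"item {item!r}: thresholds must be finite, increasing")
        for factor in self.factors + ["GP"]:
            if self._disturbance_var(factor) < 0.0:
                raise ValueError(
                    f"factor {factor!r}: regression effects leave negative "
                    "disturbance variance"
                )

    def _item_loadings(self, item: str) -> tuple[float, float]:
        factor = self.factor_of_item[item]
        k = int(item[len(factor):]) - 1
        return self.loading_plan[factor][k]

    def _gamma(self, factor: str) -> float:
        if factor == "GP":
            return self.gamma_gp
        if factor == "HI":
            return self.gamma_hi
        return 0.0

    def _covariate_gamma(self, factor: str) -> dict[str, float]:
        return {cov: eff.get(factor, 0.0) for cov, eff in self.covariate_effects.items()}

    def _disturbance_var(self, factor: str) -> float:
        explained = self._gamma(factor) ** 2 + sum(
            v * v for v in self._covariate_gamma(factor).values()
        )
        return 1.0 - explained


@dataclass
class TruthRecord:
    """Generating parameters of one synthetic cohort (recovery-test oracle)."""

    loadings_general: dict[str, float]
    loadings_specific: dict[str, float]
    gamma_gp: float
    gamma_hi: float
    covariate_effects: dict[str, dict[str, float]]
    thresholds: dict[str, tuple[float, float]]
    disturbance_corr: dict[str, float]  # "F|G" -> correlation of disturbances
    variant_effects: dict[str, float]
    seed: int

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthRecord":
        with open(path) as fh:
            raw = json.load(fh)
        raw["thresholds"] = {k: tuple(v) for k, v in raw["thresholds"].items()}
        return cls(**raw)


_CLEAN_ALLELES = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                  ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def simulate_discovery_sumstats(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[SummaryStatRecord], pd.DataFrame]:
    """Emulate a discovery GWAS at the summary-statistic level.

    Returns the records and a DataFrame of true per-allele effects
    (``variant_id``, ``b_true``; zero for non-causal variants).  The marginal
    z-score of a variant with per-allele effect b and frequency p is
    sqrt(n_eff) * b * sqrt(2 p (1-p)) plus standard-normal noise.
    A fraction of records is flagged indel / strand-ambiguous / low-INFO /
    multi-allelic to exercise the QC filters.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    m = config.n_variants
    freqs = rng.uniform(0.01, 0.5, size=m)
    n_causal = int(round(config.causal_fraction * m))
    causal = np.zeros(m, dtype=bool)
    causal[rng.choice(m, size=n_causal, replace=False)] = True
    b = np.zeros(m)
    if n_causal > 0 and config.heritability_target > 0:
        raw = rng.standard_normal(n_causal)
        var_per = 2.0 * freqs[causal] * (1.0 - freqs[causal])
        scale = math.sqrt(config.heritability_target / float(np.sum(var_per * raw * raw)))
        b[causal] = raw * scale
    z = np.sqrt(config.n_eff_discovery) * b * np.sqrt(
        2.0 * freqs * (1.0 - freqs)
    ) + rng.standard_normal(m)
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    n_art = int(round(config.artifact_fraction * m))
    artifact_idx = rng.choice(m, size=n_art, replace=False)
    artifact_kind = {idx: kind for idx, kind in
                     zip(artifact_idx, ["indel", "ambiguous", "low_info",
                                        "multiallelic"] * (n_art // 4 + 1))}

    # variants laid out in contiguous chromosome chunks, 100 kb apart
    n_chrom = min(22, m)
    chunk = math.ceil(m / n_chrom)
    records = []
    for j in range(m):
        chrom = str(j // chunk + 1)
        pos = (j % chunk) * 100_000 + 1
        kind = artifact_kind.get(j)
        ea, oa = _CLEAN_ALLELES[j % len(_CLEAN_ALLELES)]
        info, multi = 1.0, False
        if kind == "indel":
            ea, oa = "AC", "A"
        elif kind == "ambiguous":
            ea, oa = ("A", "T") if j % 2 else ("C", "G")
        elif kind == "low_info":
            info = float(rng.uniform(0.2, 0.79))
        elif kind == "multiallelic":
            multi = True
        records.append(
            SummaryStatRecord(
                variant_id=f"rs{j + 1}",
                chromosome=chrom,
                position=pos,
                effect_allele=ea,
                other_allele=oa,
                z=float(z[j]),
                p_value=float(pvals[j]),
                allele_freq=float(freqs[j]),
                n_eff=config.n_eff_discovery,
                info=info,
                is_multiallelic=multi,
            )
        )
    truth = pd.DataFrame({"variant_id": [r.variant_id for r in records], "b_true": b})
    return records, truth


def family_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic family allocation: first ``n_mz`` families are MZ."""
    rows = []
    for f in range(config.n_families):
        fam = f"F{f + 1:05d}"
        zyg = "MZ" if f < config.n_mz else "DZ"
        for t in (1, 2):
            rows.append({"child_id": f"{fam}_T{t}", "family_id": fam, "zygosity": zyg})
    return pd.DataFrame(rows)


def _draw_haplotypes(rng: np.random.Generator, freqs: np.ndarray,
                     n: int, config: SimulationConfig) -> np.ndarray:
    """n haplotypes x m variants of 0/1 alleles, optionally block-correlated."""
    m = len(freqs)
    if config.ld_block_size <= 1 or config.ld_block_r <= 0.0:
        return (rng.random((n, m)) < freqs).astype(np.int8)
    r = config.ld_block_r
    n_blocks = math.ceil(m / config.ld_block_size)
    block_u = np.repeat(rng.standard_normal((n, n_blocks)),
                        config.ld_block_size, axis=1)[:, :m]
    latent = math.sqrt(r) * block_u + math.sqrt(1.0 - r) * rng.standard_normal((n, m))
    return (latent < stats.norm.ppf(freqs)).astype(np.int8)


def simulate_twin_genotypes(
    config: SimulationConfig,
    variants: Sequence[SummaryStatRecord] | pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> GenotypePanel:
    """Draw twin genotypes by Mendelian transmission from simulated parents.

    MZ pairs receive identical transmitted alleles; DZ pairs draw their
    transmissions independently, sharing each parental allele with
    probability 1/2 (expected within-pair dosage correlation 0.5).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    if isinstance(variants, pd.DataFrame):
        meta = variants[["variant_id", "chromosome", "position",
                         "effect_allele", "other_allele"]].reset_index(drop=True)
        freqs = variants["allele_freq"].to_numpy(dtype=float)
    else:
        meta = pd.DataFrame(
            [
                {
                    "variant_id": r.variant_id,
                    "chromosome": r.chromosome,
                    "position": r.position,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                }
                for r in variants
            ]
        )
        freqs = np.array([r.allele_freq for r in variants])
    n_fam = config.n_families
    m = len(freqs)
    # parental haplotypes: mother (h0,h1), father (h2,h3) per family
    hap = [_draw_haplotypes(rng, freqs, n_fam, config) for _ in range(4)]
    mz = np.arange(n_fam) < config.n_mz

    def transmit(pick_m: np.ndarray, pick_f: np.ndarray) -> np.ndarray:
        maternal = np.where(pick_m, hap[0], hap[1])
        paternal = np.where(pick_f, hap[2], hap[3])
        return (maternal + paternal).astype(float)

    pick_m1 = rng.random((n_fam, m)) < 0.5
    pick_f1 = rng.random((n_fam, m)) < 0.5
    pick_m2 = rng.random((n_fam, m)) < 0.5
    pick_f2 = rng.random((n_fam, m)) < 0.5
    child1 = transmit(pick_m1, pick_f1)
    child2_dz = transmit(pick_m2, pick_f2)
    child2 = np.where(mz[:, None], child1, child2_dz)

    fams = family_table(config)
    dosages = np.empty((2 * n_fam, m))
    dosages[0::2] = child1
    dosages[1::2] = child2
    return GenotypePanel(
        sample_ids=fams["child_id"].tolist(), variants=meta, dosages=dosages
    )


def _true_score(panel: GenotypePanel, true_effects: pd.DataFrame) -> np.ndarray:
    """Standardized true polygenic score from per-allele generating effects."""
    b = true_effects.set_index("variant_id").reindex(
        panel.variants["variant_id"]
    )["b_true"].to_numpy()
    score = panel.dosages @ np.nan_to_num(b)
    sd = score.std()
    if sd == 0.0:
        return np.zeros_like(score)
    return (score - score.mean()) / sd


def simulate_item_responses(
    panel: GenotypePanel,
    config: SimulationConfig,
    true_effects: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate covariates, latent factors and graded item responses.

    The general factor is ``gamma_gp * PRS_true + covariate effects +
    disturbance`` with total variance 1; specific factors are analogous
    (``gamma_hi`` on the H/I factor) with disturbances orthogonal to the
    general factor's.  Latent item responses are unit-variance bifactor
    composites; the observed 0/1/2 item is the number of its thresholds the
    latent response exceeds.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 2)
    fams = family_table(config)
    n = len(fams)
    n_fam = config.n_families
    fam_idx = np.repeat(np.arange(n_fam), 2)

    prs_true = _true_score(panel, true_effects)

    # covariates (standardized scale used in the generating equations)
    sex = rng.integers(0, 2, size=n_fam)  # twins share sex, simplification
    sex = sex[fam_idx]
    age = np.repeat(rng.choice([9.0, 12.0], size=n_fam), 2)
    cov_std = {
        "sex": (sex - 0.5) / 0.5,
        "age": (age - 10.5) / 1.5,
    }
    pcs = rng.standard_normal((n, config.n_pcs))
    for i in range(config.n_pcs):
        cov_std[f"pc{i + 1}"] = pcs[:, i]

    v_fam = config.family_env_share
    rho = config.specific_corr

    def factor_scores(factor: str, shared_child: np.ndarray) -> np.ndarray:
        gam = config._gamma(factor)
        cov_gam = config._covariate_gamma(factor)
        mean_part = gam * prs_true
        for cov, g in cov_gam.items():
            if g != 0.0:
                mean_part = mean_part + g * cov_std.get(cov, 0.0)
        var_d = config._disturbance_var(factor)
        fam_part = rng.standard_normal(n_fam)[fam_idx]
        own = rng.standard_normal(n)
        if factor == "GP":
            dist = (math.sqrt(v_fam) * fam_part
                    + math.sqrt(1.0 - v_fam) * own)
        else:
            dist = (math.sqrt(v_fam) * fam_part
                    + math.sqrt(rho * (1.0 - v_fam)) * shared_child
                    + math.sqrt((1.0 - rho) * (1.0 - v_fam)) * own)
        return mean_part + math.sqrt(var_d) * dist

    shared_child = rng.standard_normal(n)  # drives cross-factor disturbance corr
    gp = factor_scores("GP", shared_child)
    specifics = {f: factor_scores(f, shared_child) for f in config.factors}

    data: dict[str, np.ndarray] = {}
    loadings_g, loadings_s, thresholds = {}, {}, {}
    for item in config.items:
        lam_g, lam_s = config._item_loadings(item)
        fac = config.factor_of_item[item]
        uniq = math.sqrt(max(0.0, 1.0 - lam_g * lam_g - lam_s * lam_s))
        ystar = lam_g * gp + lam_s * specifics[fac] + uniq * rng.standard_normal(n)
        t1, t2 = config.thresholds_for(item)
        resp = (ystar > t1).astype(float) + (ystar > t2).astype(float)
        if config.missing_rate > 0.0:
            resp[rng.random(n) < config.missing_rate] = np.nan
        data[item] = resp
        loadings_g[item] = lam_g
        loadings_s[item] = lam_s
        thresholds[item] = (t1, t2)

    cohort = fams.copy()
    cohort["sex"] = sex
    cohort["age"] = age
    for i in range(config.n_pcs):
        cohort[f"pc{i + 1}"] = pcs[:, i]
    cohort["prs_true"] = prs_true
    for item in config.items:
        cohort[item] = data[item]

    # per-dimension DSM-style symptom counts (items scored 2 = clear symptom)
    for dim in ("IA", "HI"):
        if dim in config.loading_plan:
            cols = [it for it in config.items if config.factor_of_item[it] == dim]
            cohort[f"symptoms_{dim}"] = np.nansum(
                np.column_stack([data[c] == 2.0 for c in cols]), axis=1
            ).astype(int)
        else:
            cohort[f"symptoms_{dim}"] = 0

    # ADHD diagnosis flag: high symptom count, or a random "register" flag
    # whose odds rise with the H/I factor (diagnoses track true liability)
    sym_flag = (cohort["symptoms_IA"] >= config.adhd_symptom_cutoff) | (
        cohort["symptoms_HI"] >= config.adhd_symptom_cutoff
    )
    if config.adhd_icd_prevalence > 0.0 and "HI" in specifics:
        lin = specifics["HI"] + gp
        base = stats.norm.ppf(1.0 - config.adhd_icd_prevalence) * math.sqrt(2.0)
        icd = lin + rng.standard_normal(n) * 0.5 > base
    else:
        icd = np.zeros(n, dtype=bool)
    cohort["adhd_icd"] = icd
    cohort["adhd_diagnosis"] = (sym_flag | icd).astype(bool)

    for flag in EXCLUSION_FLAGS:
        cohort[flag] = rng.random(n) < config.exclusion_prevalence / len(EXCLUSION_FLAGS)

    dist_corr = {}
    factors = config.factors
    for i, f in enumerate(factors):
        for g in factors[i + 1:]:
            vf = math.sqrt(config._disturbance_var(f) * config._disturbance_var(g))
            dist_corr[f"{f}|{g}"] = rho * (1.0 - v_fam) * vf
    truth = TruthRecord(
        loadings_general=loadings_g,
        loadings_specific=loadings_s,
        gamma_gp=config.gamma_gp,
        gamma_hi=config.gamma_hi if "HI" in config.factors else 0.0,
        covariate_effects=config.covariate_effects,
        thresholds=thresholds,
        disturbance_corr=dist_corr,
        variant_effects=dict(
            zip(true_effects["variant_id"], true_effects["b_true"].astype(float))
        ),
        seed=config.seed,
    )
    return cohort, truth


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GenotypePanel, list[SummaryStatRecord], TruthRecord]:
    """One call producing every input the analysis pipeline needs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sumstats, true_effects = simulate_discovery_sumstats(config, rng)
    panel = simulate_twin_genotypes(config, sumstats, rng)
    cohort, truth = simulate_item_responses(panel, config, true_effects, rng)
    return cohort, panel, sumstats, truth
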