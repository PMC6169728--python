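"""Polygenic risk scores from GWAS summary statistics.

Implements the discovery-to-target PRS workflow: convert GWAS z-scores to
standardized per-allele betas, apply MAF / imputation-quality / allele
filters, greedily clump variants into approximately LD-independent index
SNPs, and score target genotypes across a ladder of p-value thresholds with
PLINK ``--score no-mean-imputation`` semantics (missing genotypes drop out
of both numerator and denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStatRecord",
    "GenotypePanel",
    "PRSResult",
    "DEFAULT_THRESHOLDS",
    "standardize_beta",
    "standardize_effects",
    "filter_variants",
    "clump",
    "score_profiles",
    "impute_mz_genotypes",
]

#: Seven p-value inclusion thresholds, 0.00001 <= P_T <= 1.
DEFAULT_THRESHOLDS: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 0.01, 0.1, 0.5, 1.0)

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class SummaryStatRecord:
    """One GWAS variant: association z-score plus the metadata PRS needs."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    z: float
    p_value: float
    allele_freq: float
    n_eff: float
    info: float = 1.0
    is_multiallelic: bool = False

    @property
    def is_indel(self) -> bool:
        return len(self.effect_allele) != 1 or len(self.other_allele) != 1

    @property
    def is_ambiguous(self) -> bool:
        """Strand-ambiguous (symmetric) SNP: A/T or C/G allele pair."""
        return (self.effect_allele, self.other_allele) in _AMBIGUOUS_PAIRS

    @property
    def maf(self) -> float:
        return min(self.allele_freq, 1.0 - self.allele_freq)

    def validate(self, p_tol: float = 1e-6) -> None:
        if not (0.0 < self.allele_freq < 1.0):
            raise ValueError(f"{self.variant_id}: allele_freq must be in (0,1)")
        if self.n_eff <= 0:
            raise ValueError(f"{self.variant_id}: n_eff must be positive")
        p_implied = 2.0 * stats.norm.sf(abs(self.z))
        if not math.isclose(self.p_value, p_implied, rel_tol=1e-3, abs_tol=p_tol):
            raise ValueError(
                f"{self.variant_id}: p_value {self.p_value:g} inconsistent with "
                f"z={self.z:g} (implies {p_implied:g})"
            )


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix with explicit missingness (NaN).

    ``dosages`` holds effect-allele counts in [0, 2]; ``variants`` is a
    DataFrame with columns variant_id, chromosome, position, effect_allele,
    other_allele aligned to the dosage columns.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    imputed_from: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2.0 + 1e-9:
                raise ValueError("dosages must lie in [0, 2] or be NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return int(idx[0])

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def ld_r2(self, id_a: str, id_b: str) -> float:
        """Squared dosage correlation between two variants (pairwise complete)."""
        a = self.dosages[:, self.variant_index(id_a)]
        b = self.dosages[:, self.variant_index(id_b)]
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 2:
            return 0.0
        a, b = a[ok], b[ok]
        if a.std() == 0.0 or b.std() == 0.0:
            return 0.0
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)


def standardize_beta(z: float, n_eff: float, allele_freq: float,
                     variant_id: str = "?") -> float:
    """Per-standardized-genotype effect from a GWAS z-score.

    beta_std = z / sqrt(2 p (1-p) (n_eff + z^2)), the standard conversion
    from a summary-statistic z-score, effective sample size and effect-allele
    frequency p to an effect per standard deviation of genotype.
    """
    if not (0.0 < allele_freq < 1.0):
        raise ValueError(f"{variant_id}: allele_freq must be in (0,1), got {allele_freq}")
    if n_eff <= 0:
        raise ValueError(f"{variant_id}: n_eff must be positive, got {n_eff}")
    if not np.isfinite(z):
        raise ValueError(f"{variant_id}: non-finite z")
    return float(z / math.sqrt(2.0 * allele_freq * (1.0 - allele_freq) * (n_eff + z * z)))


def standardize_effects(records: Iterable[SummaryStatRecord]) -> pd.DataFrame:
    """Standardized betas for a collection of summary-statistic records."""
    rows = [
        (r.variant_id, standardize_beta(r.z, r.n_eff, r.allele_freq, r.variant_id))
        for r in records
    ]
    return pd.DataFrame(rows, columns=["variant_id", "beta_std"])


def filter_variants(
    records: Sequence[SummaryStatRecord],
    maf_min: float = 0.05,
    info_min: float = 0.8,
) -> tuple[list[SummaryStatRecord], dict[str, int]]:
    """Apply MAF / INFO / allele-class filters, preserving input order.

    Removal reasons are tallied with a first-match-wins precedence
    (indel, multiallelic, ambiguous, maf, info) so each excluded variant is
    counted exactly once.
    """
    kept: list[SummaryStatRecord] = []
    tally = {"indel": 0, "multiallelic": 0, "ambiguous": 0, "maf": 0, "info": 0}
    for rec in records:
        if rec.is_indel:
            tally["indel"] += 1
        elif rec.is_multiallelic:
            tally["multiallelic"] += 1
        elif rec.is_ambiguous:
            tally["ambiguous"] += 1
        elif rec.maf < maf_min:
            tally["maf"] += 1
        elif rec.info < info_min:
            tally["info"] += 1
        else:
            kept.append(rec)
    return kept, tally


def _ld_lookup(ld_source, id_a: str, id_b: str) -> float:
    if isinstance(ld_source, GenotypePanel):
        return ld_source.ld_r2(id_a, id_b)
    if isinstance(ld_source, Mapping):
        for key in ((id_a, id_b), (id_b, id_a)):
            if key in ld_source:
                return float(ld_source[key])
        raise KeyError(f"no LD entry for pair ({id_a}, {id_b})")
    raise TypeError("ld_source must be a GenotypePanel or a pair->r2 mapping")


def clump(
    records: Sequence[SummaryStatRecord],
    ld_source,
    r2_max: float = 0.1,
    window_kb: float = 1000.0,
) -> tuple[list[str], dict[str, list[str]]]:
    """Greedy LD clumping: keep index variants, absorb correlated neighbours.

    Repeatedly takes the smallest-p unassigned variant as an index and
    removes every unassigned variant on the same chromosome within
    ``window_kb`` of it whose LD r^2 with the index exceeds ``r2_max``.
    Ties in p are broken by (chromosome, position, variant_id) so the result
    is deterministic.  Returns the index-variant ids (in selection order)
    and a report mapping each index to the variants it absorbed.
    """
    if isinstance(ld_source, GenotypePanel):
        present = set(ld_source.variants["variant_id"])
        absent = [r.variant_id for r in records if r.variant_id not in present]
        if absent:
            raise KeyError(f"variants missing from LD panel: {absent}")
    order = sorted(
        records, key=lambda r: (r.p_value, str(r.chromosome), r.position, r.variant_id)
    )
    unassigned = {r.variant_id for r in records}
    window_bp = window_kb * 1000.0
    index_ids: list[str] = []
    report: dict[str, list[str]] = {}
    for rec in order:
        if rec.variant_id not in unassigned:
            continue
        unassigned.discard(rec.variant_id)
        index_ids.append(rec.variant_id)
        absorbed: list[str] = []
        for other in order:
            if other.variant_id not in unassigned:
                continue
            if str(other.chromosome) != str(rec.chromosome):
                continue
            if abs(other.position - rec.position) > window_bp:
                continue
            if _ld_lookup(ld_source, rec.variant_id, other.variant_id) > r2_max:
                unassigned.discard(other.variant_id)
                absorbed.append(other.variant_id)
        report[rec.variant_id] = absorbed
    return index_ids, report


@dataclass
class PRSResult:
    """Per-threshold polygenic scores plus the variants each threshold used."""

    table: pd.DataFrame  # columns: sample_id, p_threshold, raw, standardized, n_variants
    included: dict[float, list[str]]

    def scores(self, threshold: float, standardized: bool = True) -> pd.Series:
        sub = self.table[self.table["p_threshold"] == threshold]
        col = "standardized" if standardized else "raw"
        return sub.set_index("sample_id")[col]


def score_profiles(
    panel: GenotypePanel,
    effects: pd.DataFrame,
    sumstats: Sequence[SummaryStatRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> PRSResult:
    """Score samples at each p-value threshold (no mean imputation).

    For threshold t the raw score of a sample is
    sum(dosage_v * beta_std_v for included v with non-missing dosage)
    divided by 2 * (number of non-missing included variants), i.e. the
    PLINK 1.9 ``--score`` per-allele average combined with
    ``no-mean-imputation``.  A sample with no scorable variant at a
    threshold gets NaN, never a silent zero.  A z-standardized copy
    (cohort mean 0, SD 1 per threshold) is returned alongside.
    """
    pmap = {r.variant_id: r.p_value for r in sumstats}
    eff = effects.set_index("variant_id")["beta_std"]
    unknown = [v for v in eff.index if v not in pmap]
    if unknown:
        raise KeyError(f"effects reference variants absent from sumstats: {unknown}")
    col_of = {v: i for i, v in enumerate(panel.variants["variant_id"])}
    missing_panel = [v for v in eff.index if v not in col_of]
    if missing_panel:
        raise KeyError(f"effects reference variants absent from panel: {missing_panel}")

    rows = []
    included: dict[float, list[str]] = {}
    for t in sorted(thresholds):
        vids = [v for v in eff.index if pmap[v] <= t]
        included[t] = vids
        if not vids:
            raw = np.full(panel.n_samples, np.nan)
            nv = np.zeros(panel.n_samples, dtype=int)
        else:
            cols = [col_of[v] for v in vids]
            dose = panel.dosages[:, cols]
            betas = eff.loc[vids].to_numpy()
            ok = ~np.isnan(dose)
            num = np.nansum(dose * betas, axis=1)
            nv = ok.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                raw = np.where(nv > 0, num / (2.0 * nv), np.nan)
        mu = np.nanmean(raw) if np.isfinite(raw).any() else np.nan
        sd = np.nanstd(raw, ddof=0) if np.isfinite(raw).any() else np.nan
        std = (raw - mu) / sd if sd and np.isfinite(sd) and sd > 0 else np.full_like(raw, np.nan)
        for i, sid in enumerate(panel.sample_ids):
            rows.append((sid, t, raw[i], std[i], int(nv[i])))
    table = pd.DataFrame(
        rows, columns=["sample_id", "p_threshold", "raw", "standardized", "n_variants"]
    )
    return PRSResult(table=table, included=included)


def impute_mz_genotypes(
    panel: GenotypePanel, pairs: Mapping[str, str]
) -> GenotypePanel:
    """Add ungenotyped MZ co-twins by copying the genotyped twin's dosages.

    ``pairs`` maps new (ungenotyped) sample id -> genotyped co-twin id.
    The copy is verbatim; provenance is recorded in ``imputed_from``.
    """
    if not pairs:
        return panel
    new_rows = []
    new_ids = []
    for new_id, src_id in pairs.items():
        if new_id in panel.sample_ids:
            raise ValueError(f"sample {new_id!r} already present in panel")
        try:
            src_idx = panel.sample_index(src_id)
        except KeyError:
            raise KeyError(f"co-twin {src_id!r} for {new_id!r} not in panel") from None
        new_rows.append(panel.dosages[src_idx].copy())
        new_ids.append(new_id)
    return GenotypePanel(
        sample_ids=panel.sample_ids + new_ids,
        variants=panel.variants,
        dosages=np.vstack([panel.dosages, np.array(new_rows)]),
        imputed_from={**panel.imputed_from, **dict(pairs)},
    )
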