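"""Psychometric summaries of bifactor solutions.

Operates on a *loading table*: one row per item with the item's loading on
the general psychopathology factor (``general``) and on its specific latent
trait factor (``specific``), plus ``scale`` and ``domain`` labels.  The main
quantities are the explained common variance (ECV) of the general factor,

    ECV = 100 * sum(lambda_g^2) / (sum(lambda_g^2) + sum(lambda_s^2)),

per-domain summaries of the general loadings, and the variance in a latent
factor explained by a standardized regressor, R^2 = 100 * beta^2.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ecv",
    "r2_from_beta",
    "loading_summary",
    "validate_loading_table",
    "load_reference_loadings",
    "DEFAULT_DOMAINS",
]

#: Default mapping from symptom scale to broad symptom domain.  Scales:
#: inattention (IA), hyperactivity/impulsivity (HI), autism spectrum (ASD),
#: learning difficulties (LD), oppositional defiant (ODD), conduct (CD),
#: depression (DEP/SMFQ_DEP), and the anxiety scales (ANX and the SCARED
#: subscales PD, GAD, SAD, SA, SP).
DEFAULT_DOMAINS: dict[str, str] = {
    "IA": "neurodevelopmental",
    "HI": "neurodevelopmental",
    "ASD": "neurodevelopmental",
    "LD": "neurodevelopmental",
    "ODD": "externalizing",
    "CD": "externalizing",
    "DEP": "internalizing",
    "ANX": "internalizing",
    "SMFQ_DEP": "internalizing",
    "PD": "internalizing",
    "GAD": "internalizing",
    "SAD": "internalizing",
    "SA": "internalizing",
    "SP": "internalizing",
}

_REQUIRED_COLS = ("item", "scale", "domain", "general", "specific")


def validate_loading_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a loading table for required columns and loading bounds."""
    missing = [c for c in _REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"loading table missing columns: {missing}")
    lam = table[["general", "specific"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("loading table contains non-finite loadings")
    if np.any(np.abs(lam) > 1.0 + 1e-9):
        bad = table.loc[np.any(np.abs(lam) > 1.0 + 1e-9, axis=1), "item"].tolist()
        raise ValueError(f"standardized loadings outside [-1, 1] for items: {bad}")
    if table["domain"].isna().any():
        raise ValueError("every item needs a domain label")
    return table


def ecv(table: pd.DataFrame) -> float:
    """Explained common variance of the general factor, in percent.

    Share of the common (factor-explained) variance across all items that is
    attributable to the general factor rather than the specific trait
    factors.  Invariant to item order and to sign flips of whole factors.
    """
    validate_loading_table(table)
    ss_g = float(np.sum(np.square(table["general"].to_numpy(dtype=float))))
    ss_s = float(np.sum(np.square(table["specific"].to_numpy(dtype=float))))
    total = ss_g + ss_s
    if total == 0.0:
        raise ValueError("ECV undefined: all loadings are zero")
    return 100.0 * ss_g / total


def r2_from_beta(beta: float) -> float:
    """Variance explained (percent) by a standardized regression path."""
    if not np.isfinite(beta) or abs(beta) > 1.0:
        raise ValueError(f"standardized beta must lie in [-1, 1], got {beta!r}")
    return 100.0 * beta * beta


def loading_summary(
    table: pd.DataFrame,
    grouping: str = "domain",
    column: str = "general",
) -> pd.DataFrame:
    """Mean / min / max of a loading column per group.

    By default summarizes general-factor loadings per symptom domain
    (neurodevelopmental, externalizing, internalizing).
    """
    validate_loading_table(table)
    if grouping not in table.columns:
        raise ValueError(f"unknown grouping column {grouping!r}")
    known = set(DEFAULT_DOMAINS.values())
    if grouping == "domain":
        unknown = set(table["domain"]) - known
        if unknown:
            raise ValueError(f"unknown domain labels: {sorted(unknown)}")
    grp = table.groupby(grouping, sort=False)[column]
    out = grp.agg(["mean", "min", "max", "count"]).rename(
        columns={"count": "n_items"}
    )
    if (out["n_items"] == 0).any():
        raise ValueError("empty group in loading summary")
    return out


def load_reference_loadings(subsample: str = "atac") -> pd.DataFrame:
    """Reference loading table for the A-TAC / SMFQ / SCARED item battery.

    Standardized general and specific loadings from bifactor solutions for
    the two internalizing designs of the questionnaire battery:
    ``"atac"`` (62 items; internalizing measured by the A-TAC depression and
    anxiety scales) or ``"smfq_scared"`` (99 items; internalizing measured
    by the SMFQ and the five SCARED subscales).  Useful as worked-example
    input for :func:`ecv` and :func:`loading_summary`.
    """
    if subsample not in ("atac", "smfq_scared"):
        raise ValueError("subsample must be 'atac' or 'smfq_scared'")
    with resources.files("genfactor.data").joinpath("reference_loadings.csv").open() as fh:
        raw = pd.read_csv(fh)
    gcol = f"general_gf_{subsample}"
    scol = f"trait_gf_{subsample}"
    table = raw.loc[raw[gcol].notna(), ["item", "scale", "domain", gcol, scol]]
    table = table.rename(columns={gcol: "general", scol: "specific"})
    return validate_loading_table(table.reset_index(drop=True))
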