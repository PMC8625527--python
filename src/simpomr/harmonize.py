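"""GWAS summary-statistic handling: instrument selection and allele
harmonization for two-sample MR.

Exposure and outcome tables are pandas DataFrames with one row per SNP
and columns ``snp``, ``effect_allele``, ``other_allele``, ``beta``,
``se``, ``pval`` and optionally ``eaf`` and ``trait``.  Harmonization
aligns the outcome effect to the exposure's effect allele:

* identical alleles — kept as-is;
* swapped alleles — outcome beta sign-flipped, EAF complemented;
* strand-complement matches (direct or swapped) — treated the same;
* palindromic SNPs (A/T or C/G) — orientation inferred from the effect
  allele frequencies when both sit clearly away from 0.5 (outside
  0.5 ± ``palindromic_eaf_window``), otherwise excluded;
* anything else — excluded as an allele mismatch.

Excluded SNPs are returned separately with a reason code.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["select_instruments", "harmonize", "GWAS_COLUMNS"]

GWAS_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})

REASON_AMBIGUOUS_PALINDROMIC = "ambiguous palindromic"
REASON_ALLELE_MISMATCH = "allele mismatch"


def _check_gwas(table: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = [c for c in GWAS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{name} table missing columns: {missing}")
    if table["snp"].duplicated().any():
        dup = sorted(table.loc[table["snp"].duplicated(), "snp"].unique())
        raise ValueError(f"duplicate rsIDs in {name} table: {dup[:5]}")
    if (table["se"] <= 0).any():
        raise ValueError(f"non-positive SE in {name} table")
    alleles = set(table["effect_allele"]) | set(table["other_allele"])
    bad = alleles - set("ACGT")
    if bad:
        raise ValueError(f"invalid alleles in {name} table: {sorted(bad)}")
    return table


def select_instruments(gwas: pd.DataFrame, threshold: float = 5e-8) -> pd.DataFrame:
    """Keep SNPs with association p-value strictly below ``threshold``.

    The genome-wide significance cut 5e-8 is the conventional instrument
    filter; an empty result is legitimate (the exposure has no usable
    instruments) and is logged.
    """
    _check_gwas(gwas, "exposure")
    kept = gwas[gwas["pval"] < threshold].copy()
    if kept.empty:
        logger.warning(
            "no instruments pass p < %g (out of %d SNPs)", threshold, len(gwas)
        )
    return kept


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMIC


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_window: float = 0.08,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome effects to the exposure's effect alleles.

    Returns ``(pairs, exclusions)``.  ``pairs`` has columns ``snp``,
    ``beta_exp``, ``se_exp``, ``beta_out``, ``se_out``, ``flipped``,
    ``palindromic``; ``exclusions`` has ``snp`` and ``reason``.

    Raises ``ValueError`` when the two tables share no rsIDs.
    """
    _check_gwas(exposure, "exposure")
    _check_gwas(outcome, "outcome")
    exposure = exposure.copy()
    outcome = outcome.copy()
    for tab in (exposure, outcome):
        if "eaf" not in tab.columns:
            tab["eaf"] = np.nan
    merged = exposure.merge(
        outcome, on="snp", suffixes=("_exp", "_out"), how="inner"
    )
    if merged.empty:
        raise ValueError("no shared rsIDs between exposure and outcome tables")

    lo, hi = 0.5 - palindromic_eaf_window, 0.5 + palindromic_eaf_window
    rows, dropped = [], []
    for rec in merged.itertuples(index=False):
        ea_e, oa_e = rec.effect_allele_exp, rec.other_allele_exp
        ea_o, oa_o = rec.effect_allele_out, rec.other_allele_out
        beta_out = float(rec.beta_out)
        eaf_out = getattr(rec, "eaf_out", np.nan)
        eaf_exp = getattr(rec, "eaf_exp", np.nan)
        palindromic = _is_palindromic(ea_e, oa_e)

        if (ea_o, oa_o) == (ea_e, oa_e):
            flipped = False
        elif (ea_o, oa_o) == (oa_e, ea_e):
            flipped = True
        elif not palindromic and (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o]) == (ea_e, oa_e):
            flipped = False
        elif not palindromic and (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o]) == (oa_e, ea_e):
            flipped = True
        else:
            dropped.append({"snp": rec.snp, "reason": REASON_ALLELE_MISMATCH})
            continue

        if flipped:
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if not _isnan(eaf_out) else np.nan

        if palindromic:
            # allele labels cannot fix the strand; use frequencies
            if (
                _isnan(eaf_exp)
                or _isnan(eaf_out)
                or lo <= eaf_exp <= hi
                or lo <= eaf_out <= hi
            ):
                dropped.append({"snp": rec.snp, "reason": REASON_AMBIGUOUS_PALINDROMIC})
                continue
            if (eaf_exp < 0.5) != (eaf_out < 0.5):
                # reported on the opposite strand: flip once more
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
                flipped = not flipped

        rows.append(
            {
                "snp": rec.snp,
                "beta_exp": float(rec.beta_exp),
                "se_exp": float(rec.se_exp),
                "beta_out": beta_out,
                "se_out": float(rec.se_out),
                "flipped": flipped,
                "palindromic": palindromic,
            }
        )

    if dropped:
        logger.warning("harmonization excluded %d of %d shared SNPs", len(dropped), len(merged))
    pairs = pd.DataFrame(
        rows,
        columns=["snp", "beta_exp", "se_exp", "beta_out", "se_out", "flipped", "palindromic"],
    )
    exclusions = pd.DataFrame(dropped, columns=["snp", "reason"])
    return pairs, exclusions


def _isnan(x) -> bool:
    try:
        return bool(np.isnan(x))
    except TypeError:
        return x is None
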