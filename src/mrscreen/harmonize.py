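"""Allele harmonization and Steiger directionality filtering.

Harmonization aligns outcome effects to the exposure's effect-allele
orientation and removes SNPs that cannot be used: absent from the outcome
(no proxy search), palindromic (A/T, C/G — strand unresolvable from alleles,
removed unconditionally), allele-mismatched after optional strand-complement
reconciliation, or carrying missing effect fields.

Steiger filtering removes SNPs that explain more variance in the outcome
than in the exposure (r²_out > r²_exp, computed with the same per-SNP R²
formula on both sides), guarding against reverse causation. For binary
outcomes this R² is a log-odds-scale pseudo-R² — a documented approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .iv_selection import compute_r2
from .sumstats import SummaryStatsTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

REMOVAL_REASONS = ("not_in_outcome", "palindromic", "mismatched", "missing_values", "steiger")

#: columns of HarmonizedSet.snps; gamma/Gamma are the aligned exposure/outcome
#: effects, stored once in the exposure's allele orientation
HARMONIZED_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "gamma", "se_gamma", "pval_gamma", "eaf_exp", "n_exp",
    "Gamma", "se_Gamma", "pval_Gamma", "eaf_out", "n_out",
    "r2_exp", "r2_out",
]


def is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedSet:
    """Analysis-ready per-SNP effect pairs for one exposure–outcome pair."""

    exposure_id: str
    outcome_id: str
    outcome_type: str
    snps: pd.DataFrame
    removal_log: dict[str, int] = field(default_factory=lambda: dict.fromkeys(REMOVAL_REASONS, 0))

    @property
    def n_snp(self) -> int:
        return len(self.snps)

    @property
    def is_empty(self) -> bool:
        return len(self.snps) == 0

    def gamma(self) -> np.ndarray:
        return self.snps["gamma"].to_numpy(dtype=float)

    def se_gamma(self) -> np.ndarray:
        return self.snps["se_gamma"].to_numpy(dtype=float)

    def Gamma(self) -> np.ndarray:
        return self.snps["Gamma"].to_numpy(dtype=float)

    def se_Gamma(self) -> np.ndarray:
        return self.snps["se_Gamma"].to_numpy(dtype=float)

    def write(self, path) -> None:
        self.snps.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def harmonize(
    exposure_ivs: SummaryStatsTable,
    outcome: SummaryStatsTable,
    strand_flip: bool = True,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect-allele orientation.

    Per instrument: same alleles → keep; swapped alleles → negate outcome
    beta and complement its eaf; alleles matching only after strand
    complement (when ``strand_flip``) → complement then reapply the two
    rules; palindromic SNPs removed unconditionally; irreconcilable allele
    sets removed as mismatched; missing outcome beta/se/pval removed as
    missing values. Instruments absent from the outcome are dropped without
    proxy substitution. Removal reasons partition the removed set.
    """
    out_by_id = {r.snp_id: r for r in outcome.df.itertuples(index=False)}
    log = dict.fromkeys(REMOVAL_REASONS, 0)
    rows = []
    for exp in exposure_ivs.df.itertuples(index=False):
        rec = out_by_id.get(exp.snp_id)
        if rec is None:
            log["not_in_outcome"] += 1
            continue
        if is_palindromic(exp.effect_allele, exp.other_allele):
            log["palindromic"] += 1
            continue
        ea_o, oa_o = rec.effect_allele, rec.other_allele
        flip_sign = None
        if (ea_o, oa_o) == (exp.effect_allele, exp.other_allele):
            flip_sign = False
        elif (ea_o, oa_o) == (exp.other_allele, exp.effect_allele):
            flip_sign = True
        elif strand_flip and ea_o in COMPLEMENT and oa_o in COMPLEMENT:
            ea_c, oa_c = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
            if (ea_c, oa_c) == (exp.effect_allele, exp.other_allele):
                flip_sign = False
            elif (ea_c, oa_c) == (exp.other_allele, exp.effect_allele):
                flip_sign = True
        if flip_sign is None:
            log["mismatched"] += 1
            continue
        if any(pd.isna(v) for v in (rec.beta, rec.se, rec.pval)):
            log["missing_values"] += 1
            continue
        Gamma = -float(rec.beta) if flip_sign else float(rec.beta)
        eaf_out = float(rec.eaf) if not pd.isna(rec.eaf) else np.nan
        if flip_sign and not np.isnan(eaf_out):
            eaf_out = 1.0 - eaf_out
        rows.append({
            "snp_id": exp.snp_id, "chrom": exp.chrom, "pos": exp.pos,
            "effect_allele": exp.effect_allele, "other_allele": exp.other_allele,
            "gamma": float(exp.beta), "se_gamma": float(exp.se),
            "pval_gamma": float(exp.pval),
            "eaf_exp": float(exp.eaf) if not pd.isna(exp.eaf) else np.nan,
            "n_exp": int(exp.n),
            "Gamma": Gamma, "se_Gamma": float(rec.se), "pval_Gamma": float(rec.pval),
            "eaf_out": eaf_out, "n_out": int(rec.n),
            "r2_exp": np.nan, "r2_out": np.nan,
        })
    snps = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    return HarmonizedSet(
        exposure_ivs.trait_id, outcome.trait_id, outcome.trait_type, snps, log
    )


def steiger_filter(hset: HarmonizedSet) -> HarmonizedSet:
    """Remove SNPs explaining more variance in the outcome than the exposure.

    Deterministic per-SNP comparison: compute r²_exp and r²_out with the
    shared R² formula and drop SNPs with r²_out > r²_exp. SNPs lacking the
    eaf or n needed on either side are removed as missing values. The
    surviving frame carries the computed r² columns.
    """
    if hset.is_empty:
        return replace(hset, snps=hset.snps.copy(), removal_log=dict(hset.removal_log))
    df = hset.snps.copy()
    log = dict(hset.removal_log)
    computable = df["eaf_exp"].notna() & df["eaf_out"].notna() & (df["n_exp"] > 0) & (df["n_out"] > 0)
    log["missing_values"] = log.get("missing_values", 0) + int((~computable).sum())
    df = df.loc[computable].copy()
    if not df.empty:
        df["r2_exp"] = compute_r2(df["gamma"], df["eaf_exp"], df["se_gamma"], df["n_exp"])
        df["r2_out"] = compute_r2(df["Gamma"], df["eaf_out"], df["se_Gamma"], df["n_out"])
        keep = ~(df["r2_out"] > df["r2_exp"])
        log["steiger"] = log.get("steiger", 0) + int((~keep).sum())
        df = df.loc[keep]
    return replace(hset, snps=df.reset_index(drop=True), removal_log=log)


def harmonized_from_arrays(
    gamma, se_gamma, Gamma, se_Gamma,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    outcome_type: str = "continuous",
    snp_ids=None,
) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays.

    Convenience for estimation on already-aligned effects (e.g. simulation
    studies or externally harmonized data); metadata columns are filled with
    placeholders.
    """
    gamma = np.asarray(gamma, dtype=float)
    k = len(gamma)
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(k)]
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": ["1"] * k, "pos": np.arange(1, k + 1),
        "effect_allele": ["A"] * k, "other_allele": ["G"] * k,
        "gamma": gamma, "se_gamma": np.asarray(se_gamma, dtype=float),
        "pval_gamma": np.nan, "eaf_exp": np.nan, "n_exp": 0,
        "Gamma": np.asarray(Gamma, dtype=float),
        "se_Gamma": np.asarray(se_Gamma, dtype=float),
        "pval_Gamma": np.nan, "eaf_out": np.nan, "n_out": 0,
        "r2_exp": np.nan, "r2_out": np.nan,
    }, columns=HARMONIZED_COLUMNS)
    return HarmonizedSet(exposure_id, outcome_id, outcome_type, df)
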