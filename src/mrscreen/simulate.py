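"""Synthetic paired GWAS summary statistics for pipeline testing and calibration.

The generator emulates the data model of a two-sample MR screen of blood
metabolites against kidney phenotypes: an exposure GWAS of a standardized
(mean 0, SD 1) continuous trait in ~8,299 samples, and a much larger outcome
GWAS (10^5–10^6 samples) of a continuous trait (SD units) or a binary disease
(log-odds scale). Summary statistics are simulated directly — no
individual-level genotypes — which suffices for every downstream operation:

* each instrument SNP j gets a true exposure effect γⱼ = zⱼ·seⱼ with a
  per-SNP strength target zⱼ ~ Uniform(z_range), emulating the strongly
  selected mQTL instruments such screens retain (per-SNP F ≈ z², spanning
  roughly 10²–10³ at the defaults);
* true outcome effects follow Γⱼ = β_causal·γⱼ + αⱼ, with direct
  (pleiotropic) effects αⱼ drawn per ``pleiotropy_mode`` in the
  exposure-increasing-allele orientation;
* observed effects are the truths plus normal noise with the standard
  standardized-trait SE, seⱼ = 1/√(2·N·MAFⱼ(1−MAFⱼ)), inflated by
  1/√(cf·(1−cf)) on the log-odds scale for a binary outcome with case
  fraction cf;
* LD structure: each instrument anchors a block of ``ld_block_size`` SNPs
  whose tags carry attenuated effects √r²·γ (and √r²·α); within-block pairs
  are written to the LD table at ``ld_block_r2``, across-block LD is absent
  (independent). Remaining SNPs are unlinked nulls;
* allele labels and strands are randomly re-coded per table so the
  harmonization rules (swap, strand complement, palindromic removal) are
  exercised on realistic input.

Exposure and outcome samples are non-overlapping by construction, so effect
estimation errors are independent across the two tables. All draws derive
from ``params.seed``; the truth object plus the seed reproduces every table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import LdTable, SummaryStatsTable, _canonical_sort

PLEIOTROPY_MODES = ("none", "balanced", "directional")

PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimParams:
    """Generating parameters of one synthetic exposure–outcome pair."""

    m_snps: int = 150
    m_instruments: int = 26
    n_exp: int = 8299          # emulated metabolite-GWAS sample size
    n_out: int = 200_000
    beta_causal: float = 0.0
    pleiotropy_mode: str = "none"
    pleio_sd: float = 0.0
    pleio_mean: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    z_range: tuple[float, float] = (10.0, 40.0)  # instrument strength targets
    ld_block_size: int = 3     # instrument + tags per LD block
    ld_block_r2: float = 0.8
    outcome_type: str = "continuous"
    case_fraction: float = 0.2
    palindromic_fraction: float = 0.1
    strand_flip_fraction: float = 0.1
    n_outliers: int = 0
    outlier_shift: float = 0.0  # displacement of outlier Γ, in units of se_Γ
    seed: int = 0

    def __post_init__(self):
        if self.m_instruments > self.m_snps:
            raise ValueError("m_instruments cannot exceed m_snps")
        if self.m_instruments * self.ld_block_size > self.m_snps:
            raise ValueError("m_snps too small for the requested LD blocks")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if self.pleiotropy_mode == "balanced" and self.pleio_mean != 0.0:
            raise ValueError("balanced pleiotropy requires pleio_mean = 0")
        if not 0 < self.maf_range[0] < self.maf_range[1] <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")


@dataclass
class SimTruth:
    """Ground truth of a simulated pair, for recovery and calibration tests."""

    params: SimParams
    beta_causal: float
    instrument_ids: list[str]
    gamma_true: dict[str, float]
    alpha_true: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "params": dataclasses.asdict(self.params),
            "beta_causal": self.beta_causal,
            "instrument_ids": self.instrument_ids,
            "gamma_true": self.gamma_true,
            "alpha_true": self.alpha_true,
            "warnings": self.warnings,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _se_continuous(n: np.ndarray | float, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def simulate_pair(
    params: SimParams,
) -> tuple[SummaryStatsTable, SummaryStatsTable, LdTable, SimTruth]:
    """Generate one exposure/outcome summary-statistics pair with LD and truth."""
    rng = np.random.default_rng(params.seed)
    m = params.m_snps
    m_inst = params.m_instruments
    truth_warnings = []
    if m_inst == 0 and params.beta_causal != 0.0:
        truth_warnings.append(
            "beta_causal != 0 with no instruments: the causal effect is "
            "unidentifiable from this pair"
        )

    snp_ids = np.array([f"rs{i + 1}" for i in range(m)])
    maf = rng.uniform(*params.maf_range, size=m)

    # --- block layout: instrument blocks first, then unlinked null singletons
    block_of = np.full(m, -1, dtype=int)
    role = np.full(m, "null", dtype=object)  # instrument | tag | null
    idx = 0
    for b in range(m_inst):
        block_of[idx] = b
        role[idx] = "instrument"
        for t in range(1, params.ld_block_size):
            block_of[idx + t] = b
            role[idx + t] = "tag"
        idx += params.ld_block_size
    for singleton, i in enumerate(range(idx, m)):
        block_of[i] = m_inst + singleton

    # --- genomic coordinates: blocks tiled over chromosomes 1..22, 2 Mb apart
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    for i in range(m):
        b = block_of[i]
        chrom[i] = str(b % 22 + 1)
        within = i - np.flatnonzero(block_of == b)[0]
        pos[i] = 1_000_000 + (b // 22) * 2_000_000 + within * 5_000

    # --- true effects, defined w.r.t. the exposure-increasing base allele
    se_exp = _se_continuous(params.n_exp, maf)
    gamma_true = np.zeros(m)
    alpha_true = np.zeros(m)
    inst_mask = role == "instrument"
    z_targets = rng.uniform(*params.z_range, size=m_inst)
    gamma_true[inst_mask] = z_targets * se_exp[inst_mask]
    if params.pleiotropy_mode == "balanced":
        alpha_true[inst_mask] = rng.normal(0.0, params.pleio_sd, size=m_inst)
    elif params.pleiotropy_mode == "directional":
        alpha_true[inst_mask] = rng.normal(params.pleio_mean, params.pleio_sd, size=m_inst)
    # tags carry LD-attenuated effects of their block's instrument
    attn = np.sqrt(params.ld_block_r2)
    for i in np.flatnonzero(role == "tag"):
        anchor = np.flatnonzero(block_of == block_of[i])[0]
        gamma_true[i] = attn * gamma_true[anchor]
        alpha_true[i] = attn * alpha_true[anchor]

    if params.outcome_type == "binary":
        cf = params.case_fraction
        se_out = _se_continuous(params.n_out, maf) / np.sqrt(cf * (1.0 - cf))
    else:
        se_out = _se_continuous(params.n_out, maf)

    Gamma_true = params.beta_causal * gamma_true + alpha_true
    if params.n_outliers > 0:
        outlier_idx = np.flatnonzero(inst_mask)[: params.n_outliers]
        Gamma_true = Gamma_true.copy()
        Gamma_true[outlier_idx] += params.outlier_shift * se_out[outlier_idx]

    beta_exp = rng.normal(gamma_true, se_exp)
    beta_out = rng.normal(Gamma_true, se_out)
    from scipy import stats as _st

    pval_exp = 2.0 * _st.norm.sf(np.abs(beta_exp / se_exp))
    pval_out = 2.0 * _st.norm.sf(np.abs(beta_out / se_out))
    np.clip(pval_exp, np.finfo(float).tiny, 1.0, out=pval_exp)
    np.clip(pval_out, np.finfo(float).tiny, 1.0, out=pval_out)

    # --- allele assignment and per-table re-coding
    palindromic = rng.random(m) < params.palindromic_fraction
    pal_choice = rng.integers(0, len(PALINDROMIC_PAIRS), size=m)
    non_choice = rng.integers(0, len(NON_PALINDROMIC_PAIRS), size=m)
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    for i in range(m):
        ea[i], oa[i] = (
            PALINDROMIC_PAIRS[pal_choice[i]] if palindromic[i]
            else NON_PALINDROMIC_PAIRS[non_choice[i]]
        )
    flip_exp = rng.random(m) < 0.5       # exposure reports the other allele
    flip_out = rng.random(m) < 0.5       # outcome label choice, independent
    strand_out = rng.random(m) < params.strand_flip_fraction

    def _table(trait_id, trait_type, beta, se, pval, n, flip, strand):
        ea_t, oa_t, beta_t, eaf_t = [], [], [], []
        for i in range(m):
            a, b_ = ea[i], oa[i]
            bb, ef = beta[i], maf[i]
            if flip[i]:
                a, b_ = b_, a
                bb = -bb
                ef = 1.0 - ef
            if strand[i]:
                a, b_ = _COMPLEMENT[a], _COMPLEMENT[b_]
            ea_t.append(a)
            oa_t.append(b_)
            beta_t.append(bb)
            eaf_t.append(ef)
        df = pd.DataFrame({
            "snp_id": snp_ids, "chrom": chrom, "pos": pos,
            "effect_allele": ea_t, "other_allele": oa_t,
            "eaf": eaf_t, "beta": beta_t, "se": se, "pval": pval,
            "n": np.full(m, n, dtype=np.int64),
        })
        return SummaryStatsTable(trait_id, trait_type, _canonical_sort(df))

    no_strand = np.zeros(m, dtype=bool)
    exposure = _table("exposure", "continuous", beta_exp, se_exp, pval_exp,
                      params.n_exp, flip_exp, no_strand)
    outcome = _table("outcome", params.outcome_type, beta_out, se_out, pval_out,
                     params.n_out, flip_out, strand_out)

    ld = LdTable()
    for b in range(m_inst):
        members = np.flatnonzero(block_of == b)
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                ld.add(snp_ids[members[x]], snp_ids[members[y]], params.ld_block_r2)

    truth = SimTruth(
        params=params,
        beta_causal=params.beta_causal,
        instrument_ids=[str(s) for s in snp_ids[inst_mask]],
        gamma_true={str(s): float(v) for s, v in zip(snp_ids, gamma_true) if v != 0.0},
        alpha_true={str(s): float(v) for s, v in zip(snp_ids, alpha_true) if v != 0.0},
        warnings=truth_warnings,
    )
    return exposure, outcome, ld, truth


def scenario_suite() -> dict[str, SimParams]:
    """Named presets covering the scenarios the screen must handle.

    * ``null`` — instruments but no causal effect, no pleiotropy: type-I
      error and Q/Egger/PRESSO calibration.
    * ``causal`` — β = 0.2 with 50 strong instruments and a 5×10⁵-sample
      outcome: unbiased recovery and CI coverage.
    * ``balanced_pleiotropy`` — zero-mean direct effects (InSIDE holds):
      IVW stays unbiased, Egger intercept centres on 0, Q detects the
      overdispersion.
    * ``directional_pleiotropy`` — same spread with a nonzero mean: IVW is
      biased, the Egger intercept centres on ``pleio_mean`` and its test has
      power above the balanced counterpart.
    * ``weak_instruments`` — strength targets straddling F = 10 so the
      weak-instrument filter has real work to do.
    * ``one_outlier`` — a single instrument with a gross (10 SE) direct
      effect on the outcome, for the MR-PRESSO global and outlier tests.

    Replace the ``seed`` (``dataclasses.replace``) before use.
    """
    return {
        "null": SimParams(m_snps=150, m_instruments=26, n_out=200_000,
                          beta_causal=0.0, pleiotropy_mode="none"),
        # ld_block_size=1: the recovery scenario uses 50 *independent* valid
        # instruments so it isolates estimator behaviour; with tag SNPs in the
        # blocks, clumping sometimes crowns a winner's-curse-inflated tag as
        # index, an (realistic) selection bias the estimators do not correct.
        "causal": SimParams(m_snps=250, m_instruments=50, n_out=500_000,
                            beta_causal=0.2, pleiotropy_mode="none",
                            ld_block_size=1),
        "balanced_pleiotropy": SimParams(
            m_snps=150, m_instruments=26, n_out=200_000, beta_causal=0.1,
            pleiotropy_mode="balanced", pleio_sd=0.005),
        "directional_pleiotropy": SimParams(
            m_snps=150, m_instruments=26, n_out=200_000, beta_causal=0.1,
            pleiotropy_mode="directional", pleio_sd=0.005, pleio_mean=0.01),
        "weak_instruments": SimParams(
            m_snps=200, m_instruments=40, n_out=200_000, beta_causal=0.1,
            z_range=(2.0, 4.5), palindromic_fraction=0.0),
        "one_outlier": SimParams(
            m_snps=120, m_instruments=20, n_out=200_000, beta_causal=0.1,
            pleiotropy_mode="none", n_outliers=1, outlier_shift=10.0),
    }
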