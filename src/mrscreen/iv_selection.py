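"""Instrument selection for one exposure.

Stages: genome-wide p-value screen (strict ``p < threshold``), greedy LD
clumping against a supplied LD table, per-SNP variance explained (R²) and
F statistics, and weak-instrument removal (drop F < 10, i.e. retain F ≥ 10).

The F statistic follows F = R²·(N − k − 1) / [k·(1 − R²)] and R² follows
R² = 2β²·EAF(1−EAF) / [2β²·EAF(1−EAF) + 2·SE²·N·EAF(1−EAF)].
Filtering uses the per-SNP convention k = 1 (the only reading under which an
F threshold can remove individual SNPs); the joint-k F of a whole instrument
set is additionally exposed via :func:`joint_f`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingEafError
from .sumstats import LdTable, SummaryStatsTable, _canonical_sort

logger = logging.getLogger(__name__)

DEFAULT_PVAL_THRESHOLD = 1e-5
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000
DEFAULT_F_MIN = 10.0


def filter_by_pvalue(
    table: SummaryStatsTable, threshold: float = DEFAULT_PVAL_THRESHOLD
) -> SummaryStatsTable:
    """Retain rows with ``pval < threshold`` (strict). Empty output is valid."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    mask = table.df["pval"].to_numpy() < threshold
    return SummaryStatsTable(table.trait_id, table.trait_type, table.df.loc[mask].copy())


def clump(
    table: SummaryStatsTable,
    ld: LdTable,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
) -> SummaryStatsTable:
    """Greedy LD clumping: keep index SNPs, prune their correlated neighbours.

    Repeatedly takes the most significant remaining SNP as an index and
    removes all remaining SNPs on the same chromosome within ±``window_kb``
    of it whose LD r² with the index is ≥ ``r2_max``. Pairs absent from the
    LD table count as independent (r² = 0). Ties in p are broken by
    (chrom, pos) ascending, so the result is deterministic; output is in
    canonical genomic order.
    """
    if not 0.0 < r2_max < 1.0:
        raise ValueError(f"r2_max must be in (0, 1), got {r2_max}")
    if window_kb <= 0:
        raise ValueError(f"window_kb must be positive, got {window_kb}")
    df = table.df
    if df.empty:
        return SummaryStatsTable(table.trait_id, table.trait_type, df.copy())
    order = df.sort_values(
        ["pval", "chrom", "pos"], kind="mergesort"
    )[["snp_id", "chrom", "pos"]].to_numpy()
    window_bp = int(window_kb) * 1000
    alive = dict.fromkeys(range(len(order)), True)
    kept_ids = []
    for i in range(len(order)):
        if not alive[i]:
            continue
        snp_i, chrom_i, pos_i = order[i]
        kept_ids.append(snp_i)
        for j in range(i + 1, len(order)):
            if not alive[j]:
                continue
            snp_j, chrom_j, pos_j = order[j]
            if chrom_j != chrom_i or abs(int(pos_j) - int(pos_i)) > window_bp:
                continue
            if ld.r2(snp_i, snp_j) >= r2_max:
                alive[j] = False
    out = _canonical_sort(df.loc[df["snp_id"].isin(set(kept_ids))].copy())
    return SummaryStatsTable(table.trait_id, table.trait_type, out)


def compute_ld_from_dosages(genotypes: np.ndarray, snp_ids: list[str]) -> LdTable:
    """LD table from an n×m genotype-dosage matrix (values in [0, 2]).

    r² is the squared Pearson correlation between dosage columns. Columns with
    zero variance cannot enter a correlation; their pairs are omitted and the
    column ids recorded in ``LdTable.dropped_snps``.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[1] != len(snp_ids):
        raise ValueError("genotypes must be n×m with one column per snp_id")
    if g.shape[1] < 2:
        raise ValueError("need at least two SNP columns")
    variances = g.var(axis=0)
    ok = variances > 0
    table = LdTable()
    table.dropped_snps = [s for s, v in zip(snp_ids, ok) if not v]
    if table.dropped_snps:
        logger.info("zero-variance dosage column(s) omitted: %s", table.dropped_snps)
    idx = np.flatnonzero(ok)
    if len(idx) >= 2:
        corr = np.corrcoef(g[:, idx], rowvar=False)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                r2 = min(float(corr[a, b] ** 2), 1.0)
                table.add(snp_ids[idx[a]], snp_ids[idx[b]], r2)
    return table


def compute_r2(beta, eaf, se, n):
    """Per-SNP variance in the exposure explained by the SNP.

    R² = 2β²·EAF(1−EAF) / [2β²·EAF(1−EAF) + 2·SE²·N·EAF(1−EAF)].
    The numerator is the variance attributable to the SNP; the denominator
    adds the unexplained variance implied by the estimate's standard error.
    Vectorized over array inputs; EAF is required (symmetric in EAF ↔ 1−EAF).
    """
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(np.isnan(eaf)):
        raise MissingEafError("eaf is required to compute R^2")
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("eaf must be in (0, 1)")
    if np.any(se <= 0) or np.any(n <= 0):
        raise ValueError("se and n must be positive")
    het = 2.0 * eaf * (1.0 - eaf)
    num = beta**2 * het
    r2 = num / (num + se**2 * n * het)
    return r2 if r2.ndim else float(r2)


def compute_f(r2, n, k: int = 1):
    """F statistic: F = R²·(N − k − 1) / [k·(1 − R²)]; requires N > k + 1."""
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.any((r2 < 0) | (r2 >= 1)):
        raise ValueError("r2 must be in [0, 1)")
    if np.any(n <= k + 1):
        raise ValueError(f"sample size must exceed k + 1 = {k + 1}")
    f = r2 * (n - k - 1) / (k * (1.0 - r2))
    return f if f.ndim else float(f)


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure with per-SNP strength metrics.

    ``metrics`` carries one row per instrument (snp_id, r2, f_stat; k = 1).
    ``selection_log`` counts SNPs removed at each selection stage.
    """

    exposure_id: str
    table: SummaryStatsTable
    metrics: pd.DataFrame
    selection_log: dict[str, int] = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.table)


def build_instrument_set(
    table: SummaryStatsTable, selection_log: dict[str, int] | None = None
) -> InstrumentSet:
    """Attach per-SNP R² and F (k = 1) to an already-selected table."""
    df = table.df
    if df["eaf"].isna().any():
        raise MissingEafError(
            f"{table.trait_id}: eaf missing for "
            f"{int(df['eaf'].isna().sum())} SNP(s); cannot compute R^2/F"
        )
    if df.empty:
        metrics = pd.DataFrame(columns=["snp_id", "r2", "f_stat"])
    else:
        r2 = compute_r2(df["beta"], df["eaf"], df["se"], df["n"])
        f = compute_f(r2, df["n"].to_numpy(), k=1)
        metrics = pd.DataFrame(
            {"snp_id": df["snp_id"].to_numpy(), "r2": np.atleast_1d(r2), "f_stat": np.atleast_1d(f)}
        )
    return InstrumentSet(table.trait_id, table, metrics, dict(selection_log or {}))


def joint_f(iset: InstrumentSet) -> float:
    """F of the whole instrument set with k = its size (joint convention)."""
    if iset.n_snp == 0:
        raise ValueError("empty instrument set has no joint F")
    r2_total = float(iset.metrics["r2"].sum())
    r2_total = min(r2_total, 1.0 - 1e-12)
    n = float(iset.table.df["n"].min())
    return compute_f(r2_total, n, k=iset.n_snp)


def drop_weak_instruments(iset: InstrumentSet, f_min: float = DEFAULT_F_MIN) -> InstrumentSet:
    """Remove instruments with F < ``f_min``; F exactly at the floor is kept."""
    keep = iset.metrics.loc[iset.metrics["f_stat"] >= f_min, "snp_id"]
    n_removed = iset.n_snp - len(keep)
    log = dict(iset.selection_log)
    log["weak_instruments"] = log.get("weak_instruments", 0) + n_removed
    return InstrumentSet(
        iset.exposure_id,
        iset.table.subset(keep),
        iset.metrics.loc[iset.metrics["f_stat"] >= f_min].reset_index(drop=True),
        log,
    )


def select_instruments(
    table: SummaryStatsTable,
    ld: LdTable,
    pval_threshold: float = DEFAULT_PVAL_THRESHOLD,
    clump_r2: float = DEFAULT_CLUMP_R2,
    clump_window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
    f_min: float | None = DEFAULT_F_MIN,
) -> InstrumentSet:
    """Convenience composition: p-screen → clump → metrics (→ weak-IV filter).

    Pass ``f_min=None`` to defer the weak-instrument filter (the screening
    pipeline applies it after harmonization and Steiger filtering).
    """
    log: dict[str, int] = {}
    sig = filter_by_pvalue(table, pval_threshold)
    log["pvalue_filter"] = len(table) - len(sig)
    clumped = clump(sig, ld, clump_r2, clump_window_kb)
    log["clumping"] = len(sig) - len(clumped)
    iset = build_instrument_set(clumped, log)
    if f_min is not None:
        iset = drop_weak_instruments(iset, f_min)
    return iset
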