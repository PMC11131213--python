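"""Reading, validation and writing of GWAS summary-statistics and LD tables.

This module is the single source of truth for column semantics:

* coordinates are 1-based (GWAS summary-statistics convention);
* alleles are single upper-case nucleotides — indels and multi-character
  alleles are rejected at read time (the pipeline operates on SNPs only);
* ``beta`` is the per-effect-allele effect on the trait: log-odds for binary
  traits, SD units for standardized continuous traits;
* missing values are encoded as ``NA`` on disk; only ``eaf`` may be missing
  in a valid record (frequency-dependent computations then raise downstream);
* duplicate ``snp_id`` entries keep the record with the smallest p-value.

On-disk format: UTF-8 tab-separated with a header of canonical column names
(``snp_id chrom pos effect_allele other_allele eaf beta se pval n``).
A ``column_map`` lets readers consume other dialects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

NUCLEOTIDES = frozenset("ACGT")
TRAIT_TYPES = ("binary", "continuous")

#: strict p/z consistency: flag when the stated p-value differs from
#: 2*Phi(-|beta/se|) by more than this absolutely AND by more than 5% relatively.
P_CONSISTENCY_ABS_TOL = 1e-4
P_CONSISTENCY_REL_TOL = 0.05


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in NUCLEOTIDES or self.other_allele not in NUCLEOTIDES:
            raise ValueError(f"{self.snp_id}: alleles must be single A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if not 0 < self.pval <= 1:
            raise ValueError(f"{self.snp_id}: pval must be in (0, 1]")
        if self.eaf is not None and not np.isnan(self.eaf) and not 0 < self.eaf < 1:
            raise ValueError(f"{self.snp_id}: eaf must be in (0, 1) when present")


@dataclass
class ReadLog:
    """Row-level bookkeeping from :func:`read_sumstats`."""

    n_input: int = 0
    n_coercion_dropped: int = 0
    n_invalid_dropped: int = 0
    n_duplicates_collapsed: int = 0


class SummaryStatsTable:
    """An ordered, snp_id-unique collection of :class:`SnpAssociation` records.

    Backed by a :class:`pandas.DataFrame` with the canonical columns; the
    trait type is always set explicitly, never inferred from the data.
    """

    def __init__(self, trait_id: str, trait_type: str, df: pd.DataFrame,
                 read_log: ReadLog | None = None):
        if trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}, got {trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing canonical column(s): {', '.join(missing)}")
        if df["snp_id"].duplicated().any():
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_id(s): {dups[:5]}")
        self.trait_id = trait_id
        self.trait_type = trait_type
        self.df = df.reset_index(drop=True)
        self.read_log = read_log or ReadLog(n_input=len(df))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryStatsTable):
            return NotImplemented
        return (
            self.trait_id == other.trait_id
            and self.trait_type == other.trait_type
            and _frames_equal(self.df, other.df)
        )

    def records(self) -> list[SnpAssociation]:
        out = []
        for row in self.df.itertuples(index=False):
            eaf = None if pd.isna(row.eaf) else float(row.eaf)
            out.append(SnpAssociation(
                snp_id=row.snp_id, chrom=str(row.chrom), pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                eaf=eaf, beta=float(row.beta), se=float(row.se),
                pval=float(row.pval), n=int(row.n)))
        return out

    def subset(self, mask_or_ids) -> "SummaryStatsTable":
        """New table restricted to a boolean mask or an iterable of snp_ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and (
            len(mask_or_ids) == len(self.df)
            and pd.api.types.is_bool_dtype(np.asarray(mask_or_ids))
        ):
            sub = self.df.loc[np.asarray(mask_or_ids)]
        else:
            ids = set(mask_or_ids)
            sub = self.df.loc[self.df["snp_id"].isin(ids)]
        return SummaryStatsTable(self.trait_id, self.trait_type, sub.copy())


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    # records form a set keyed by snp_id: compare in canonical order
    if len(a) != len(b):
        return False
    a = _canonical_sort(a[CANONICAL_COLUMNS])
    b = _canonical_sort(b[CANONICAL_COLUMNS])
    try:
        pd.testing.assert_frame_equal(a, b, check_dtype=False)
    except AssertionError:
        return False
    return True


def _canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    # chromosome sorted numerically where possible ("2" before "10", X/Y last)
    key = df["chrom"].astype(str).map(_chrom_rank)
    return (
        df.assign(_ck=key)
        .sort_values(["_ck", "pos", "snp_id"], kind="mergesort")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )


def _chrom_rank(c: str) -> float:
    try:
        return float(int(c))
    except ValueError:
        return {"X": 23.0, "Y": 24.0, "MT": 25.0, "M": 25.0}.get(c.upper(), 26.0)


def read_sumstats(
    path: str | Path,
    trait_type: str,
    trait_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> SummaryStatsTable:
    """Read a tab-separated summary-statistics file.

    Parameters
    ----------
    path
        TSV file with a header row.
    trait_type
        ``"binary"`` or ``"continuous"``; must be stated, never guessed.
    trait_id
        Defaults to the file stem.
    column_map
        Maps canonical column names to the file's column names for
        non-canonical dialects, e.g. ``{"snp_id": "SNP", "pval": "P"}``.

    Rows that fail numeric coercion or violate record invariants (non-positive
    ``se``, out-of-range p-value, non-ACGT or identical alleles) are dropped
    and counted in the returned table's ``read_log``. Duplicate snp_ids keep
    the smallest p-value. Records are returned in canonical (chrom, pos,
    snp_id) order, so the reader is permutation-stable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    if raw.empty and raw.columns.size == 0:
        raise ValueError(f"{path}: empty file")

    cmap = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = cmap.get(canon, canon)
        if src not in raw.columns:
            raise ValueError(f"{path}: missing mandatory column {src!r} (for {canon!r})")
        rename[src] = canon
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS].copy()
    log = ReadLog(n_input=len(df))
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)

    coercible = df[["pos", "beta", "se", "pval", "n"]].notna().all(axis=1)
    log.n_coercion_dropped = int((~coercible).sum())
    df = df.loc[coercible]

    valid = (
        (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & df["effect_allele"].isin(NUCLEOTIDES)
        & df["other_allele"].isin(NUCLEOTIDES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
        & (df["n"] > 0)
    )
    log.n_invalid_dropped = int((~valid).sum())
    if log.n_invalid_dropped or log.n_coercion_dropped:
        logger.info(
            "%s: dropped %d rows failing coercion, %d violating invariants",
            path.name, log.n_coercion_dropped, log.n_invalid_dropped,
        )
    df = df.loc[valid]

    # duplicate markers: keep the most significant record (smallest p),
    # ties broken deterministically by (chrom, pos)
    before = len(df)
    df = df.sort_values(["pval", "chrom", "pos"], kind="mergesort").drop_duplicates(
        "snp_id", keep="first"
    )
    log.n_duplicates_collapsed = before - len(df)

    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    df = _canonical_sort(df)
    return SummaryStatsTable(trait_id or path.stem, trait_type, df, read_log=log)


def write_sumstats(table: SummaryStatsTable, path: str | Path) -> Path:
    """Write a table as canonical TSV; ``read(write(t)) == t`` on all fields."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty summary-statistics table")
    path = Path(path)
    df = _canonical_sort(table.df[CANONICAL_COLUMNS].copy())
    # %.17g preserves doubles exactly across the round trip
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
    return path


@dataclass
class ValidationReport:
    """Counts of suspicious records; validation never mutates the table."""

    n_records: int = 0
    missing_eaf: int = 0
    allele_violations: int = 0
    se_violations: int = 0
    pval_violations: int = 0
    p_z_inconsistencies: int = 0
    strict: bool = False

    @property
    def clean(self) -> bool:
        return (
            self.allele_violations == 0
            and self.se_violations == 0
            and self.pval_violations == 0
            and self.p_z_inconsistencies == 0
        )


def validate_sumstats(table: SummaryStatsTable, strict: bool = False) -> ValidationReport:
    """Report-only validation.

    Under ``strict``, each record's p-value is checked against the two-sided
    normal p implied by beta/se; a record is inconsistent when the absolute
    difference exceeds ``P_CONSISTENCY_ABS_TOL`` and the relative difference
    exceeds ``P_CONSISTENCY_REL_TOL``.
    """
    df = table.df
    rep = ValidationReport(n_records=len(df), strict=strict)
    rep.missing_eaf = int(df["eaf"].isna().sum())
    allele_ok = (
        df["effect_allele"].isin(NUCLEOTIDES)
        & df["other_allele"].isin(NUCLEOTIDES)
        & (df["effect_allele"] != df["other_allele"])
    )
    rep.allele_violations = int((~allele_ok).sum())
    rep.se_violations = int((df["se"] <= 0).sum())
    rep.pval_violations = int(((df["pval"] <= 0) | (df["pval"] > 1)).sum())
    if strict:
        ok = (df["se"] > 0)
        z = np.abs(df.loc[ok, "beta"] / df.loc[ok, "se"])
        p_implied = 2.0 * stats.norm.sf(z)
        p_stated = df.loc[ok, "pval"].to_numpy()
        abs_diff = np.abs(p_stated - p_implied)
        rel_diff = abs_diff / np.maximum(p_implied, np.finfo(float).tiny)
        rep.p_z_inconsistencies = int(
            ((abs_diff > P_CONSISTENCY_ABS_TOL) & (rel_diff > P_CONSISTENCY_REL_TOL)).sum()
        )
    return rep


class LdTable:
    """Pairwise LD (r²) lookups with implied symmetric closure.

    Missing pairs are treated as independent (r² = 0) by consumers such as
    clumping; a SNP with itself has r² = 1.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in pairs:
            self.add(a, b, float(r2))
        self.dropped_snps: list[str] = []

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 must be in [0, 1], got {r2} for ({a}, {b})")
        if a == b:
            return
        key = self._key(a, b)
        if key in self._r2 and self._r2[key] != r2:
            raise ValueError(f"conflicting r2 for pair {key}: {self._r2[key]} vs {r2}")
        self._r2[key] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def read(cls, path: str | Path) -> "LdTable":
        df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        for col in ("snp_a", "snp_b", "r2"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing LD column {col!r}")
        return cls(df[["snp_a", "snp_b", "r2"]].itertuples(index=False, name=None))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        rows = sorted((a, b, r2) for (a, b), r2 in self._r2.items())
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
        return path
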