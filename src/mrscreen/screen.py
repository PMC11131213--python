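"""Exposure × outcome screen orchestration and two-tier significance calls.

Per pair, the pipeline runs in the narrative order of the instrument-selection
procedure: p-value screen → LD clumping → allele harmonization → Steiger
directionality filter → weak-instrument (F) filter → estimation (IVW,
MR-Egger, weighted median) → sensitivity diagnostics → classification.
The F filter's position is configurable (``f_filter_stage``); the default
applies it last, after Steiger filtering.

Classification (two tiers):

* ``bonferroni_significant`` — IVW p below α divided by the number of
  exposures tested (0.05/1400 = 3.571×10⁻⁵ at the defaults);
* ``nominal_significant`` — p < α in all three estimators, with a shared
  effect direction, and no heterogeneity or pleiotropy detected (Cochran's Q,
  Egger intercept and MR-PRESSO global p all > α; a diagnostic that could not
  run passes vacuously but is recorded);
* otherwise ``null``; pairs with an empty intermediate stage are ``skipped``
  with the stage recorded.

Every stochastic step draws from a per-pair seed derived deterministically
from the screen seed and the pair index, so whole-screen outputs are
byte-reproducible regardless of evaluation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DegenerateDesignError,
    InsufficientInstrumentsError,
    MissingEafError,
)
from .harmonize import HarmonizedSet, harmonize, steiger_filter
from .iv_selection import (
    build_instrument_set,
    clump,
    compute_f,
    drop_weak_instruments,
    filter_by_pvalue,
)
from .mr_estimators import MRResult, egger, ivw, weighted_median
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import LdTable, SummaryStatsTable

CLASSIFICATIONS = ("bonferroni_significant", "nominal_significant", "null", "skipped")


@dataclass
class ScreenConfig:
    """All screen-level tuning in one place; ``seed`` is mandatory."""

    seed: int
    pval_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    alpha: float = 0.05
    n_tests_for_bonferroni: int = 1400
    n_boot: int = 1000
    n_sim: int = 1000
    strand_flip: bool = True
    random_effects: bool = True
    f_filter_stage: str = "after_steiger"  # or "before_harmonize"
    include_loo: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("pval_threshold", "clump_r2", "f_min", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.f_filter_stage not in ("after_steiger", "before_harmonize"):
            raise ValueError("f_filter_stage must be 'after_steiger' or 'before_harmonize'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold α / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class PairResult:
    """Everything the screen records about one exposure–outcome pair."""

    exposure_id: str
    outcome_id: str
    outcome_type: str
    results: dict[str, MRResult] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    n_snp_final: int = 0
    classification: str = "skipped"
    skip_stage: str | None = None
    selection_log: dict[str, int] = field(default_factory=dict)
    removal_log: dict[str, int] = field(default_factory=dict)
    method_errors: dict[str, str] = field(default_factory=dict)


def classify(pair: PairResult, cfg: ScreenConfig) -> str:
    """Two-tier significance call; a pure function of the stored results."""
    if pair.classification == "skipped" and not pair.results:
        return "skipped"
    ivw_res = pair.results.get("ivw")
    if ivw_res is None:
        return "skipped"
    if ivw_res.pval < bonferroni_threshold(cfg.alpha, cfg.n_tests_for_bonferroni):
        return "bonferroni_significant"
    methods = [pair.results.get(m) for m in ("ivw", "egger", "weighted_median")]
    if any(m is None for m in methods):
        return "null"
    if not all(m.pval < cfg.alpha for m in methods):
        return "null"
    signs = {np.sign(m.beta) for m in methods}
    if len(signs) != 1 or signs == {0.0}:
        return "null"
    sens = pair.sensitivity
    if sens is not None:
        if sens.q_pval is not None and sens.q_pval <= cfg.alpha:
            return "null"
        if sens.egger_intercept_p is not None and sens.egger_intercept_p <= cfg.alpha:
            return "null"
        if sens.presso_global_p is not None and sens.presso_global_p <= cfg.alpha:
            return "null"
    return "nominal_significant"


def _skipped(exposure, outcome, stage, selection_log=None, removal_log=None) -> PairResult:
    return PairResult(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        outcome_type=outcome.trait_type,
        classification="skipped",
        skip_stage=stage,
        selection_log=dict(selection_log or {}),
        removal_log=dict(removal_log or {}),
    )


def run_pair(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LdTable,
    cfg: ScreenConfig,
    seed: int | None = None,
) -> PairResult:
    """Full pipeline for one pair; failures downgrade to ``skipped``."""
    seed = cfg.seed if seed is None else seed
    log: dict[str, int] = {}

    sig = filter_by_pvalue(exposure, cfg.pval_threshold)
    log["pvalue_filter"] = len(exposure) - len(sig)
    if len(sig) == 0:
        return _skipped(exposure, outcome, "pvalue_filter", log)

    clumped = clump(sig, ld, cfg.clump_r2, cfg.clump_window_kb)
    log["clumping"] = len(sig) - len(clumped)

    if cfg.f_filter_stage == "before_harmonize":
        try:
            iset = drop_weak_instruments(build_instrument_set(clumped, log), cfg.f_min)
        except MissingEafError:
            return _skipped(exposure, outcome, "weak_instruments_missing_eaf", log)
        log = iset.selection_log
        clumped = iset.table
        if len(clumped) == 0:
            return _skipped(exposure, outcome, "weak_instruments", log)

    hset = harmonize(clumped, outcome, strand_flip=cfg.strand_flip)
    if hset.is_empty:
        return _skipped(exposure, outcome, "harmonize", log, hset.removal_log)

    hset = steiger_filter(hset)
    if hset.is_empty:
        return _skipped(exposure, outcome, "steiger", log, hset.removal_log)

    if cfg.f_filter_stage == "after_steiger":
        # per-SNP F (k = 1) from the exposure-side variance explained,
        # which the Steiger step has already computed
        f = compute_f(hset.snps["r2_exp"].to_numpy(), hset.snps["n_exp"].to_numpy(), k=1)
        keep = f >= cfg.f_min
        log["weak_instruments"] = int((~keep).sum())
        hset = dataclasses.replace(
            hset, snps=hset.snps.loc[keep].reset_index(drop=True),
            removal_log=dict(hset.removal_log),
        )
        if hset.is_empty:
            return _skipped(exposure, outcome, "weak_instruments", log, hset.removal_log)

    pair = PairResult(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        outcome_type=outcome.trait_type,
        n_snp_final=hset.n_snp,
        selection_log=log,
        removal_log=dict(hset.removal_log),
    )
    pair.results["ivw"] = ivw(hset, random_effects=cfg.random_effects)
    for name, fit in (
        ("egger", lambda: egger(hset)),
        ("weighted_median", lambda: weighted_median(hset, n_boot=cfg.n_boot, seed=seed)),
    ):
        try:
            pair.results[name] = fit()
        except (InsufficientInstrumentsError, DegenerateDesignError) as exc:
            pair.method_errors[name] = str(exc)
    pair.sensitivity = sensitivity_report(
        hset, n_sim=cfg.n_sim, seed=seed, alpha=cfg.alpha, include_loo=cfg.include_loo
    )
    pair.classification = classify(pair, cfg)
    return pair


def pair_seed(screen_seed: int, pair_index: int) -> int:
    """Deterministic per-pair sub-seed (< 2^31), independent of run order."""
    return int(np.random.SeedSequence([screen_seed, pair_index]).generate_state(1)[0] % (2**31))


@dataclass
class ScreenResult:
    pairs: list[PairResult]
    cfg: ScreenConfig
    exposure_ids: list[str]
    outcome_ids: list[str]

    def long_table(self) -> pd.DataFrame:
        """One row per (pair, method) with sensitivity columns repeated."""
        rows = []
        for p in self.pairs:
            base = {
                "exposure_id": p.exposure_id,
                "outcome_id": p.outcome_id,
                "outcome_type": p.outcome_type,
                "n_snp": p.n_snp_final,
                "classification": p.classification,
                "skip_stage": p.skip_stage or "",
            }
            sens = p.sensitivity
            sens_cols = {
                "q_stat": sens.q_stat if sens else None,
                "q_pval": sens.q_pval if sens else None,
                "egger_intercept": sens.egger_intercept if sens else None,
                "egger_intercept_p": sens.egger_intercept_p if sens else None,
                "presso_global_p": sens.presso_global_p if sens else None,
            }
            if not p.results:
                rows.append({**base, "method": "", "beta": None, "se": None,
                             "ci_low": None, "ci_high": None, "pval": None,
                             "or_": None, "or_low": None, "or_high": None, **sens_cols})
            for method, res in p.results.items():
                rows.append({
                    **base, "method": method, "beta": res.beta, "se": res.se,
                    "ci_low": res.ci_low, "ci_high": res.ci_high, "pval": res.pval,
                    "or_": res.or_, "or_low": res.or_low, "or_high": res.or_high,
                    **sens_cols,
                })
        return pd.DataFrame(rows)

    def matrix(self) -> pd.DataFrame:
        """Exposures × outcomes signed-significance matrix.

        ±2 Bonferroni-significant, ±1 nominal (sign = IVW effect direction),
        0 null, blank (NA) skipped.
        """
        mat = pd.DataFrame(
            np.nan, index=self.exposure_ids, columns=self.outcome_ids, dtype=float
        )
        for p in self.pairs:
            if p.classification == "skipped":
                continue
            sign = float(np.sign(p.results["ivw"].beta)) or 1.0
            code = {"bonferroni_significant": 2.0, "nominal_significant": 1.0, "null": 0.0}[
                p.classification
            ]
            mat.loc[p.exposure_id, p.outcome_id] = sign * code
        mat.index.name = "exposure_id"
        return mat


def run_screen(
    exposures: list[SummaryStatsTable],
    outcomes: list[SummaryStatsTable],
    ld: LdTable,
    cfg: ScreenConfig,
) -> ScreenResult:
    """Evaluate every exposure × outcome pair under per-pair sub-seeds."""
    if not exposures or not outcomes:
        raise ValueError("need at least one exposure and one outcome")
    pairs = []
    idx = 0
    for exp in exposures:
        for out in outcomes:
            pairs.append(run_pair(exp, out, ld, cfg, seed=pair_seed(cfg.seed, idx)))
            idx += 1
    return ScreenResult(
        pairs, cfg, [e.trait_id for e in exposures], [o.trait_id for o in outcomes]
    )


def write_screen_outputs(result: ScreenResult, outdir: str | Path) -> dict[str, Path]:
    """Write ``results_long.tsv``, ``matrix.tsv`` and ``screen_log.json``.

    Output is deterministic (no timestamps, fixed float formatting), so a
    re-run with the same config is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results_long": outdir / "results_long.tsv",
        "matrix": outdir / "matrix.tsv",
        "log": outdir / "screen_log.json",
    }
    result.long_table().to_csv(
        paths["results_long"], sep="\t", index=False, na_rep="NA", float_format="%.10g"
    )
    result.matrix().to_csv(paths["matrix"], sep="\t", na_rep="NA", float_format="%.10g")
    log = {
        "config": dataclasses.asdict(result.cfg),
        "pairs": [
            {
                "exposure_id": p.exposure_id,
                "outcome_id": p.outcome_id,
                "classification": p.classification,
                "skip_stage": p.skip_stage,
                "n_snp": p.n_snp_final,
                "selection_log": p.selection_log,
                "removal_log": p.removal_log,
                "method_errors": p.method_errors,
            }
            for p in result.pairs
        ],
    }
    paths["log"].write_text(json.dumps(log, indent=2, sort_keys=True))
    return paths
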