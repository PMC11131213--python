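"""Replication studies over the synthetic scenarios.

Each function runs the actual pipeline (simulation → instrument selection →
harmonization → Steiger and weak-IV filtering → estimation/diagnostics) many
times and aggregates operating characteristics: type-I error under the null,
bias/coverage under a causal effect, and pleiotropy discrimination. These are
the computations behind the package's calibration claims; the analysis
drivers and the acceptance script report their outputs.

All replicate seeds are derived additively from the caller's base seed, so
every study is exactly reproducible; keep base seeds below 2^30 to leave room
for the offsets.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet, harmonize, steiger_filter
from .iv_selection import clump, compute_f, filter_by_pvalue
from .mr_estimators import egger, ivw
from .screen import ScreenConfig, run_screen, write_screen_outputs
from .sensitivity import cochran_q, presso_global
from .simulate import SimParams, scenario_suite, simulate_pair


def pipeline_harmonized_set(params: SimParams, f_min: float = 10.0) -> HarmonizedSet:
    """Simulate one pair and push it through selection and harmonization."""
    exposure, outcome, ld, _ = simulate_pair(params)
    sig = filter_by_pvalue(exposure, 1e-5)
    clumped = clump(sig, ld)
    hset = steiger_filter(harmonize(clumped, outcome))
    if not hset.is_empty and f_min is not None:
        f = compute_f(hset.snps["r2_exp"].to_numpy(), hset.snps["n_exp"].to_numpy(), k=1)
        hset = dataclasses.replace(
            hset, snps=hset.snps.loc[f >= f_min].reset_index(drop=True),
            removal_log=dict(hset.removal_log),
        )
    return hset


def null_calibration(
    n_reps: int = 1000, seed: int = 20_240_528, presso_n_sim: int = 200
) -> dict:
    """Type-I error of IVW, the Egger intercept test and MR-PRESSO, plus the
    goodness of fit of Cochran's Q p-values to their null uniform law, under
    the ``null`` scenario (instruments, no causal effect, no pleiotropy)."""
    base = scenario_suite()["null"]
    alpha = 0.05
    rej = {"ivw": 0, "egger_intercept": 0, "presso": 0}
    q_pvals = []
    n_snps = []
    for i in range(n_reps):
        hset = pipeline_harmonized_set(dataclasses.replace(base, seed=seed + i))
        n_snps.append(hset.n_snp)
        rej["ivw"] += ivw(hset).pval < alpha
        rej["egger_intercept"] += egger(hset).intercept_p < alpha
        rej["presso"] += (
            presso_global(hset, n_sim=presso_n_sim, seed=seed + n_reps + i).global_p
            < alpha
        )
        q_pvals.append(cochran_q(hset)[2])
    return {
        "n_reps": n_reps,
        "ivw_rejection_rate": rej["ivw"] / n_reps,
        "egger_intercept_rejection_rate": rej["egger_intercept"] / n_reps,
        "presso_rejection_rate": rej["presso"] / n_reps,
        "q_uniformity_ks_pvalue": float(stats.kstest(q_pvals, "uniform").pvalue),
        "mean_n_snp": float(np.mean(n_snps)),
    }


def causal_recovery(n_reps: int = 200, seed: int = 20_240_529) -> dict:
    """Bias and 95% CI coverage of IVW under the ``causal`` scenario
    (true effect 0.2, 50 valid instruments, 5×10⁵-sample outcome)."""
    base = scenario_suite()["causal"]
    truth = base.beta_causal
    estimates, covered = [], 0
    for i in range(n_reps):
        hset = pipeline_harmonized_set(dataclasses.replace(base, seed=seed + i))
        res = ivw(hset)
        estimates.append(res.beta)
        covered += res.ci_low <= truth <= res.ci_high
    estimates = np.asarray(estimates)
    return {
        "n_reps": n_reps,
        "true_beta": truth,
        "mean_ivw_estimate": float(estimates.mean()),
        "sd_ivw_estimate": float(estimates.std(ddof=1)),
        "ci95_coverage": covered / n_reps,
    }


def pleiotropy_discrimination(n_reps: int = 150, seed: int = 20_240_530) -> dict:
    """Mean MR-Egger intercept and intercept-test power under directional vs
    balanced pleiotropy with equal direct-effect spread."""
    suite = scenario_suite()
    out = {"n_reps": n_reps,
           "pleio_mean_directional": suite["directional_pleiotropy"].pleio_mean}
    for name in ("balanced_pleiotropy", "directional_pleiotropy"):
        intercepts, power = [], 0
        for i in range(n_reps):
            hset = pipeline_harmonized_set(
                dataclasses.replace(suite[name], seed=seed + i))
            res = egger(hset)
            intercepts.append(res.intercept)
            power += res.intercept_p < 0.05
        tag = name.split("_")[0]
        intercepts = np.asarray(intercepts)
        out[f"mean_intercept_{tag}"] = float(intercepts.mean())
        out[f"sem_intercept_{tag}"] = float(intercepts.std(ddof=1) / np.sqrt(n_reps))
        out[f"intercept_power_{tag}"] = power / n_reps
    return out


def demo_screen_tables(seed: int, n_exposures: int = 10, n_outcomes: int = 2):
    """Synthetic screen inputs: a mix of causal and null exposures against
    shared outcomes, with one common LD table."""
    suite = scenario_suite()
    exposures, outcomes = [], []
    ld = None
    for i in range(n_exposures):
        preset = "causal" if i % 5 == 0 else "null"
        params = dataclasses.replace(suite[preset], seed=seed + i,
                                     m_snps=150, m_instruments=26,
                                     ld_block_size=suite[preset].ld_block_size)
        e, o, ld_i, _ = simulate_pair(params)
        e.trait_id = f"metabolite_{i + 1:02d}"
        exposures.append(e)
        if ld is None:
            ld = ld_i
        if len(outcomes) < n_outcomes:
            o.trait_id = f"outcome_{len(outcomes) + 1}"
            outcomes.append(o)
    return exposures, outcomes, ld


def screen_determinism(seed: int, workdir: str | Path, n_sim: int = 200,
                       n_boot: int = 200) -> dict:
    """Run the demo screen twice with one config and compare output bytes."""
    workdir = Path(workdir)
    exposures, outcomes, ld = demo_screen_tables(seed)
    cfg = ScreenConfig(seed=seed, n_sim=n_sim, n_boot=n_boot,
                       n_tests_for_bonferroni=len(exposures))
    paths_a = write_screen_outputs(run_screen(exposures, outcomes, ld, cfg),
                                   workdir / "run_a")
    paths_b = write_screen_outputs(run_screen(exposures, outcomes, ld, cfg),
                                   workdir / "run_b")
    identical = all(paths_a[k].read_bytes() == paths_b[k].read_bytes() for k in paths_a)
    return {
        "n_pairs": len(exposures) * len(outcomes),
        "identical": identical,
        "paths": {k: str(v) for k, v in paths_a.items()},
    }
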