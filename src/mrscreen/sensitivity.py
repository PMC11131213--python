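"""Heterogeneity and pleiotropy diagnostics for a harmonized instrument set.

* Cochran's Q over per-SNP Wald ratios, centred on the **fixed-effect** IVW
  estimate (the standard definition, regardless of the headline IVW variant),
  with a chi-square(J−1) upper-tail p-value.
* The MR-Egger intercept test (average directional pleiotropy).
* The MR-PRESSO global test: an observed weighted residual sum of squares
  around leave-one-out IVW fits, compared against its parametric simulation
  distribution; per-SNP outlier p-values come from each SNP's own simulated
  residual² distribution, Bonferroni-adjusted. The (1 + #exceed)/(1 + n_sim)
  convention avoids zero p-values.
* Leave-one-out IVW, flagging SNPs whose exclusion flips the estimate's sign
  or moves its p-value across the significance threshold.

All diagnostics are read-only on the harmonized set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .harmonize import HarmonizedSet
from .mr_estimators import egger, ivw

DEFAULT_N_SIM = 1000
DEFAULT_ALPHA = 0.05
PRESSO_MIN_SNPS = 4


def cochran_q(hset: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q = Σ wⱼ(θⱼ − θ̂)², wⱼ = γⱼ²/se_Γⱼ², θ̂ the fixed-effect IVW.

    Returns (q_stat, q_df, q_pval) with q_df = J − 1 and an upper-tail
    chi-square p-value. θ̂ is always re-estimated from the given set.
    """
    if hset.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    g, G, seG = hset.gamma(), hset.Gamma(), hset.se_Gamma()
    theta = G / g
    w = g**2 / seG**2
    center = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - center) ** 2))
    df = hset.n_snp - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(hset: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, se, p) from the MR-Egger fit; p < α flags pleiotropy."""
    res = egger(hset)
    return float(res.intercept), float(res.intercept_se), float(res.intercept_p)


def _loo_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, vectorized over the left-out SNP."""
    sxy = np.sum(w * g * G)
    sxx = np.sum(w * g * g)
    return (sxy - w * g * G) / (sxx - w * g * g)


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    n_sim: int
    outlier_p: pd.Series  # Bonferroni-adjusted per-SNP outlier p-values


def presso_global(
    hset: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed: int | None = None,
) -> PressoResult:
    """MR-PRESSO global pleiotropy test.

    Observed statistic: RSS = Σⱼ (Γⱼ − β₍₋ⱼ₎γⱼ)² / se_Γⱼ² with β₍₋ⱼ₎ the
    leave-one-out fixed-effect IVW slope. Null distribution: for each of
    ``n_sim`` replicates draw γⱼ* ~ N(γⱼ, se_γⱼ) and Γⱼ* ~ N(β₍₋ⱼ₎γⱼ, se_Γⱼ)
    and recompute the same statistic (including re-fitting the leave-one-out
    slopes on the simulated data). Global p = (1 + #{RSS* ≥ RSS}) / (1 + n_sim);
    per-SNP outlier p-values are computed analogously from each SNP's
    simulated residual² distribution and Bonferroni-adjusted across SNPs.
    The result is invariant to SNP ordering and reproducible under the seed.
    """
    if hset.n_snp < PRESSO_MIN_SNPS:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs >= {PRESSO_MIN_SNPS} instruments, got {hset.n_snp}"
        )
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if seed is None:
        raise ValueError("seed is mandatory for the simulation p-value")
    # canonical snp order so permutations of the input cannot change draws
    order = np.argsort(hset.snps["snp_id"].to_numpy(), kind="stable")
    ids = hset.snps["snp_id"].to_numpy()[order]
    g = hset.gamma()[order]
    seg = hset.se_gamma()[order]
    G = hset.Gamma()[order]
    seG = hset.se_Gamma()[order]
    w = 1.0 / seG**2
    j = len(g)

    beta_loo = _loo_slopes(g, G, w)
    resid2_obs = w * (G - beta_loo * g) ** 2
    rss_obs = float(np.sum(resid2_obs))

    rng = np.random.default_rng(seed)
    gs = rng.normal(g, seg, size=(n_sim, j))
    Gs = rng.normal(beta_loo * g, seG, size=(n_sim, j))
    ws = np.broadcast_to(w, (n_sim, j))
    sxy = np.sum(ws * gs * Gs, axis=1, keepdims=True)
    sxx = np.sum(ws * gs * gs, axis=1, keepdims=True)
    beta_loo_sim = (sxy - ws * gs * Gs) / (sxx - ws * gs * gs)
    resid2_sim = ws * (Gs - beta_loo_sim * gs) ** 2
    rss_sim = resid2_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    exceed = np.sum(resid2_sim >= resid2_obs[None, :], axis=0)
    p_per_snp = (1 + exceed) / (1 + n_sim)
    outlier_p = pd.Series(np.minimum(1.0, p_per_snp * j), index=ids, name="outlier_p")
    return PressoResult(rss_obs, global_p, n_sim, outlier_p)


def presso_outlier_corrected(
    hset: HarmonizedSet, presso: PressoResult, alpha: float = DEFAULT_ALPHA
):
    """Optional PRESSO follow-up: IVW re-estimated without significant outliers.

    Returns (corrected MRResult or None, list of removed snp_ids); None when
    no SNP's adjusted outlier p falls below ``alpha`` or too few SNPs remain.
    """
    outliers = set(presso.outlier_p.index[presso.outlier_p < alpha])
    if not outliers:
        return None, []
    keep = ~hset.snps["snp_id"].isin(outliers)
    if keep.sum() < 2:
        return None, sorted(outliers)
    from dataclasses import replace

    sub = replace(hset, snps=hset.snps.loc[keep].reset_index(drop=True),
                  removal_log=dict(hset.removal_log))
    return ivw(sub), sorted(outliers)


def leave_one_out(hset: HarmonizedSet, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """IVW re-estimated with each SNP excluded in turn.

    Returns one row per excluded SNP (snp_id, beta, se, pval, influential);
    a SNP is influential when its exclusion flips the sign of the estimate
    or moves the p-value across ``alpha`` relative to the full-set IVW.
    """
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 instruments")
    full = ivw(hset)
    rows = []
    from dataclasses import replace

    for i in range(hset.n_snp):
        sub = replace(
            hset,
            snps=hset.snps.drop(index=hset.snps.index[i]).reset_index(drop=True),
            removal_log=dict(hset.removal_log),
        )
        res = ivw(sub)
        influential = (np.sign(res.beta) != np.sign(full.beta)) or (
            (res.pval < alpha) != (full.pval < alpha)
        )
        rows.append({
            "snp_id": hset.snps["snp_id"].iloc[i],
            "beta": res.beta, "se": res.se, "pval": res.pval,
            "influential": bool(influential),
        })
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Bundle of all diagnostics for one exposure–outcome pair.

    Diagnostics that cannot run on small sets are None and recorded in
    ``skipped``: Q needs ≥ 2 SNPs, the Egger intercept and leave-one-out
    need ≥ 3, MR-PRESSO needs ≥ 4. Flags are pure threshold functions of the
    available p-values at level ``alpha``; an unavailable test cannot raise
    a flag (vacuously passes).
    """

    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_global_rss: float | None = None
    presso_global_p: float | None = None
    presso_n_sim: int | None = None
    loo: pd.DataFrame | None = None
    alpha: float = DEFAULT_ALPHA
    skipped: list = field(default_factory=list)

    @property
    def heterogeneity_detected(self) -> bool:
        return self.q_pval is not None and self.q_pval < self.alpha

    @property
    def pleiotropy_detected(self) -> bool:
        egger_hit = self.egger_intercept_p is not None and self.egger_intercept_p < self.alpha
        presso_hit = self.presso_global_p is not None and self.presso_global_p < self.alpha
        return egger_hit or presso_hit


def sensitivity_report(
    hset: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    include_loo: bool = True,
) -> SensitivityReport:
    """Run every diagnostic the set size permits and collect the results."""
    rep = SensitivityReport(alpha=alpha)
    if hset.n_snp >= 2:
        rep.q_stat, rep.q_df, rep.q_pval = cochran_q(hset)
    else:
        rep.skipped.append("cochran_q")
    if hset.n_snp >= 3:
        rep.egger_intercept, rep.egger_intercept_se, rep.egger_intercept_p = (
            egger_intercept_test(hset)
        )
    else:
        rep.skipped.append("egger_intercept")
    if hset.n_snp >= PRESSO_MIN_SNPS:
        presso = presso_global(hset, n_sim=n_sim, seed=seed)
        rep.presso_global_rss = presso.rss_obs
        rep.presso_global_p = presso.global_p
        rep.presso_n_sim = presso.n_sim
    else:
        rep.skipped.append("presso_global")
    if include_loo and hset.n_snp >= 3:
        rep.loo = leave_one_out(hset, alpha=alpha)
    elif include_loo:
        rep.skipped.append("leave_one_out")
    return rep
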