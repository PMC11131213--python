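"""Causal estimators for a harmonized instrument set.

Three estimators over per-SNP effect pairs (γⱼ ± se_γⱼ on the exposure,
Γⱼ ± se_Γⱼ on the outcome):

* ``ivw`` — inverse-variance-weighted: weighted least squares of Γ on γ
  through the origin with weights 1/se_Γ², equivalently the 1/var-weighted
  average of per-SNP Wald ratios Γⱼ/γⱼ with weights γⱼ²/se_Γⱼ². The default
  is the multiplicative random-effects variant: the SE is inflated by the
  weighted residual scale √φ² (J−1 df) floored at 1, so under-dispersion is
  never allowed to shrink the SE. P-values are two-sided normal.
* ``egger`` — the same weighted regression with an intercept, after orienting
  every SNP so γⱼ > 0. The slope is a pleiotropy-robust causal estimate under
  InSIDE; the intercept estimates average directional pleiotropy. SEs carry
  the √φ² (J−2 df) floor-at-1 scale; inference uses t(J−2).
* ``weighted_median`` — the weighted median of per-SNP Wald ratios with
  weights γⱼ²/se_Γⱼ² (the leading-order inverse variance of the ratio),
  consistent when ≥ 50% of weight comes from valid instruments; its SE is a
  parametric bootstrap (seed mandatory), p two-sided normal.

For binary outcomes, causal estimates are on the log-odds scale and the
``or_`` fields carry exp(beta) with exponentiated CI bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    EmptyInstrumentSetError,
    InsufficientInstrumentsError,
)
from .harmonize import HarmonizedSet

DEFAULT_N_BOOT = 1000


@dataclass
class MRResult:
    """One estimator's output for one exposure–outcome pair."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    or_: float | None = None
    or_low: float | None = None
    or_high: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def with_odds_ratio(self) -> "MRResult":
        self.or_ = float(np.exp(self.beta))
        self.or_low = float(np.exp(self.ci_low))
        self.or_high = float(np.exp(self.ci_high))
        return self


def _finish(result: MRResult, outcome_type: str) -> MRResult:
    return result.with_odds_ratio() if outcome_type == "binary" else result


def _two_sided_normal_p(z: float) -> float:
    # floored at the smallest subnormal so p stays in (0, 1]
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny)))


def wald_ratio(snp, outcome_type: str = "continuous") -> MRResult:
    """Single-SNP causal estimate: beta = Γ/γ, se = se_Γ/|γ| (delta method)."""
    gamma, Gamma, se_Gamma = float(snp["gamma"]), float(snp["Gamma"]), float(snp["se_Gamma"])
    if gamma == 0.0:
        raise ZeroDivisionError("Wald ratio undefined for gamma = 0")
    beta = Gamma / gamma
    se = se_Gamma / abs(gamma)
    z = stats.norm.ppf(0.975)
    res = MRResult(
        method="wald",
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        pval=_two_sided_normal_p(beta / se),
        n_snp=1,
    )
    return _finish(res, outcome_type)


def ivw(hset: HarmonizedSet, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted estimate (multiplicative random effects).

    Closed form: beta = Σ γⱼΓⱼ/se_Γⱼ² / Σ γⱼ²/se_Γⱼ²;
    se = √(1/Σ γⱼ²/se_Γⱼ²) · max(1, √φ²) where φ² is the weighted residual
    mean square on J−1 df. ``random_effects=False`` drops the φ term
    (fixed-effect). A single SNP delegates to :func:`wald_ratio`.
    """
    if hset.is_empty:
        raise EmptyInstrumentSetError(f"{hset.exposure_id} vs {hset.outcome_id}: no instruments")
    if hset.n_snp == 1:
        res = wald_ratio(hset.snps.iloc[0], hset.outcome_type)
        res.method = "ivw"
        return res
    g, G, seG = hset.gamma(), hset.Gamma(), hset.se_Gamma()
    w = 1.0 / seG**2
    sxx = float(np.sum(w * g * g))
    beta = float(np.sum(w * g * G)) / sxx
    scale = 1.0
    if random_effects:
        j = hset.n_snp
        phi2 = float(np.sum(w * (G - beta * g) ** 2)) / (j - 1)
        scale = max(1.0, np.sqrt(phi2))
    se = np.sqrt(1.0 / sxx) * scale
    z975 = stats.norm.ppf(0.975)
    res = MRResult(
        method="ivw",
        beta=beta,
        se=se,
        ci_low=beta - z975 * se,
        ci_high=beta + z975 * se,
        pval=_two_sided_normal_p(beta / se),
        n_snp=hset.n_snp,
    )
    return _finish(res, hset.outcome_type)


def egger(hset: HarmonizedSet) -> MRResult:
    """MR-Egger regression: weighted fit of Γ on γ with an intercept.

    SNPs are oriented so γⱼ > 0 (both effects negated where γⱼ < 0). The
    2-parameter WLS fit uses weights 1/se_Γⱼ²; both SEs are scaled by
    max(1, √φ²) with φ² on J−2 df, and p-values/CIs use t(J−2).
    """
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs >= 3 instruments, got {hset.n_snp}"
        )
    g, G, seG = hset.gamma(), hset.Gamma(), hset.se_Gamma()
    flip = np.sign(g)
    flip[flip == 0] = 1.0
    g, G = g * flip, G * flip
    w = 1.0 / seG**2
    sw = float(np.sum(w))
    swx = float(np.sum(w * g))
    swxx = float(np.sum(w * g * g))
    det = sw * swxx - swx**2
    # collinear design: weighted variance of gamma vanishes
    if det <= 1e-12 * sw * swxx or np.allclose(g, g[0]):
        raise DegenerateDesignError("all oriented exposure effects equal; Egger fit undefined")
    swy = float(np.sum(w * G))
    swxy = float(np.sum(w * g * G))
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    j = hset.n_snp
    resid = G - intercept - slope * g
    phi2 = float(np.sum(w * resid**2)) / (j - 2)
    scale = max(1.0, np.sqrt(phi2))
    se_slope = np.sqrt(sw / det) * scale
    se_intercept = np.sqrt(swxx / det) * scale
    tq = stats.t.ppf(0.975, j - 2)
    p_slope = float(min(1.0, 2.0 * stats.t.sf(abs(slope / se_slope), j - 2)))
    p_intercept = float(min(1.0, 2.0 * stats.t.sf(abs(intercept / se_intercept), j - 2)))
    res = MRResult(
        method="egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pval=p_slope,
        n_snp=j,
        intercept=intercept,
        intercept_se=se_intercept,
        intercept_p=p_intercept,
    )
    return _finish(res, hset.outcome_type)


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative midpoint weights sⱼ = cum wⱼ − wⱼ/2."""
    order = np.argsort(theta, kind="stable")
    theta = theta[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, theta))


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> MRResult:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Ratios θⱼ = Γⱼ/γⱼ are weighted by γⱼ²/se_Γⱼ²; SNPs with γⱼ = 0 are
    excluded (logged on the result as ``n_snp`` shrinkage). The SE is the SD
    of the estimate over ``n_boot`` parametric resamples γⱼ* ~ N(γⱼ, se_γⱼ),
    Γⱼ* ~ N(Γⱼ, se_Γⱼ); a seed is mandatory for reproducibility.
    """
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 3 instruments, got {hset.n_snp}"
        )
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap standard error")
    g, seg = hset.gamma(), hset.se_gamma()
    G, seG = hset.Gamma(), hset.se_Gamma()
    nonzero = g != 0.0
    if not np.all(nonzero):
        g, seg, G, seG = g[nonzero], seg[nonzero], G[nonzero], seG[nonzero]
    j = len(g)
    if j < 3:
        raise InsufficientInstrumentsError("fewer than 3 instruments with nonzero gamma")
    theta = G / g
    w = g**2 / seG**2
    beta = _weighted_median(theta, w)

    rng = np.random.default_rng(seed)
    gs = rng.normal(g, seg, size=(n_boot, j))
    Gs = rng.normal(G, seG, size=(n_boot, j))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        gb = gs[b]
        ok = gb != 0.0
        boots[b] = _weighted_median(Gs[b][ok] / gb[ok], gb[ok] ** 2 / seG[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    z975 = stats.norm.ppf(0.975)
    pval = (_two_sided_normal_p(beta / se) if se > 0
            else (1.0 if beta == 0 else float(np.finfo(float).tiny)))
    res = MRResult(
        method="weighted_median",
        beta=beta,
        se=se,
        ci_low=beta - z975 * se,
        ci_high=beta + z975 * se,
        pval=pval,
        n_snp=j,
    )
    return _finish(res, hset.outcome_type)
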