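"""Univariate two-sample Mendelian randomisation estimators and diagnostics.

All estimators operate on a :class:`~mrmediate.sumstats_io.HarmonisedSet`
whose variants are oriented to the exposure-increasing allele.  The default
inference follows the conventions of the standard two-sample MR software
family: inverse-variance weighting with multiplicative random effects
floored at the fixed-effects value, normal-approximation p-values for every
estimator except MR-Egger, which uses t inference on k - 2 degrees of
freedom (the small-instrument regime where the difference matters).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import MRConfig
from .errors import EstimationError, InputError
from .ld_clump import LDMatrix, count_rule, greedy_clump
from .sumstats_io import HarmonisedSet, SummaryStatSet, harmonise, select_instruments

log = logging.getLogger(__name__)

Z95 = 1.959964  # normal 97.5% quantile, the 95% CI multiplier


@dataclass
class MRResult:
    """One estimator's causal-effect estimate (per SD of exposure; log-odds
    scale for binary outcomes)."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_variants: int


@dataclass
class HeterogeneityStats:
    """Cochran's Q against a chi-squared reference, plus the I2_GX
    measurement-error statistic for the exposure associations."""

    q: float
    df: int
    pval: float
    i2gx: float | None = None


def _normal_result(method: str, estimate: float, se: float, k: int) -> MRResult:
    if se > 0:
        z = estimate / se
        pval = float(max(2 * stats.norm.sf(abs(z)), 1e-300))
    else:
        pval = 1e-300 if estimate != 0 else 1.0
    return MRResult(method, float(estimate), float(se),
                    float(estimate - Z95 * se), float(estimate + Z95 * se), pval, k)


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MRResult:
    """Single-variant causal estimate: ratio of outcome to exposure effect.

    The standard error is first-order: se_out / |beta_exp|.
    """
    if beta_exp == 0:
        raise EstimationError("Wald ratio undefined: exposure beta is zero")
    est = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return _normal_result("wald", est, se, 1)


def _ratio_arrays(h: HarmonisedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant ratio estimates and first-order ratio weights; variants
    with zero exposure beta are excluded with a warning."""
    bx, by, so = h.beta_exp, h.beta_out, h.se_out
    ok = bx != 0
    if not ok.all():
        log.warning("%d variant(s) with zero exposure beta excluded from ratio-based estimator",
                    int((~ok).sum()))
    theta = by[ok] / bx[ok]
    w = (bx[ok] / so[ok]) ** 2
    return theta, w


def ivw(h: HarmonisedSet, random_effects: bool = True) -> MRResult:
    """Inverse-variance weighted estimate.

    Equivalent to a no-intercept weighted regression of outcome betas on
    exposure betas with weights 1/se_out^2.  Under multiplicative random
    effects the SE is scaled by sqrt(Q/(k-1)), floored at 1.
    """
    k = h.n_variants
    if k == 0:
        raise EstimationError("empty harmonised set")
    if k == 1:
        return wald_ratio(h.beta_exp[0], h.se_exp[0], h.beta_out[0], h.se_out[0])
    bx, by, so = h.beta_exp, h.beta_out, h.se_out
    w = 1.0 / so**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise EstimationError("degenerate instruments: all exposure betas are zero")
    est = float(np.sum(w * bx * by)) / denom
    q = float(np.sum(w * (by - est * bx) ** 2))
    scale = max(1.0, np.sqrt(q / (k - 1))) if random_effects else 1.0
    se = np.sqrt(1.0 / denom) * scale
    return _normal_result("ivw", est, se, k)


def cochran_q(h: HarmonisedSet, estimate: float) -> HeterogeneityStats:
    """Heterogeneity of the per-variant ratio estimates around ``estimate``.

    Uses first-order ratio weights (se_out/beta_exp)^-2; df = k - 1.
    """
    if h.n_variants < 2:
        raise EstimationError("Cochran's Q needs at least 2 variants")
    theta, w = _ratio_arrays(h)
    q = float(np.sum(w * (theta - estimate) ** 2))
    df = len(theta) - 1
    return HeterogeneityStats(q, df, float(stats.chi2.sf(q, df)))


def i2gx(h: HarmonisedSet) -> float:
    """I^2 statistic for the exposure associations (no-measurement-error
    diagnostic for MR-Egger); 1 - I2_GX bounds the relative attenuation of
    the Egger slope towards the null."""
    if h.n_variants < 2:
        raise EstimationError("I2_GX needs at least 2 variants")
    se = h.se_exp
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise InputError("I2_GX requires finite positive exposure SEs")
    v = 1.0 / se**2
    bx = h.beta_exp
    mean = np.sum(v * bx) / np.sum(v)
    q_gx = float(np.sum(v * (bx - mean) ** 2))
    k = h.n_variants
    if q_gx <= 0:
        return 0.0
    return max(0.0, (q_gx - (k - 1)) / q_gx)


def egger_regression(
    h: HarmonisedSet, random_effects: bool = True
) -> tuple[MRResult, MRResult, HeterogeneityStats]:
    """MR-Egger: weighted regression of outcome on exposure betas with an
    unconstrained intercept (weights 1/se_out^2).

    The slope is a pleiotropy-adjusted causal estimate; the intercept
    estimates average directional pleiotropy and its test is the Egger
    intercept test.  Inference is t with k - 2 df.  Requires orientation to
    the exposure-increasing allele (done by harmonisation) because the fit
    is not invariant to allele coding.
    """
    k = h.n_variants
    if k < 3:
        raise EstimationError("MR-Egger needs at least 3 variants")
    bx, by, so = h.beta_exp, h.beta_out, h.se_out
    if np.allclose(bx, bx[0]):
        raise EstimationError("rank-deficient Egger design: all exposure betas equal")
    w = 1.0 / so**2
    x = np.column_stack([np.ones(k), bx])
    xtw = x.T * w
    xtwx = xtw @ x
    coef = np.linalg.solve(xtwx, xtw @ by)
    resid = by - x @ coef
    q = float(np.sum(w * resid**2))
    df = k - 2
    scale2 = max(1.0, q / df) if random_effects else 1.0
    cov = scale2 * np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov))
    tq = float(stats.t.ppf(0.975, df))

    def _t_result(method: str, est: float, se: float) -> MRResult:
        pval = float(max(2 * stats.t.sf(abs(est / se), df), 1e-300)) if se > 0 \
            else (1e-300 if est else 1.0)
        return MRResult(method, float(est), float(se),
                        float(est - tq * se), float(est + tq * se), pval, k)

    slope = _t_result("egger-slope", coef[1], ses[1])
    intercept = _t_result("egger-intercept", coef[0], ses[0])
    het = HeterogeneityStats(q, df, float(stats.chi2.sf(q, df)))
    return slope, intercept, het


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="mergesort")
    th = theta[order]
    ww = w[order] / np.sum(w[order])
    s = np.cumsum(ww)
    p = 100.0 * (s - ww / 2.0)
    return float(np.interp(50.0, p, th))


def _bootstrap_se(h: HarmonisedSet, point_fn, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample betas from N(beta, se) in both
    samples and recompute the point estimate."""
    rng = np.random.default_rng(seed)
    bx, sx, by, so = h.beta_exp, h.se_exp, h.beta_out, h.se_out
    k = len(bx)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, so)
        ests[b] = point_fn(bxs, bys, so)
    return float(np.std(ests, ddof=1))


def weighted_median(h: HarmonisedSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of the per-variant ratio estimates; consistent when
    at least half the weight comes from valid instruments.  SE by seeded
    parametric bootstrap."""
    theta, w = _ratio_arrays(h)
    if len(theta) < 3:
        raise EstimationError("weighted median needs at least 3 usable variants")
    est = _weighted_median_point(theta, w)

    def point(bx, by, so):
        ok = bx != 0
        return _weighted_median_point(by[ok] / bx[ok], (bx[ok] / so[ok]) ** 2)

    se = _bootstrap_se(h, point, n_boot, seed)
    res = _normal_result("weighted-median", est, se, h.n_variants)
    return res


def _mode_point(theta: np.ndarray, w: np.ndarray, phi: float, n_grid: int) -> float:
    """Argmax of the Gaussian-kernel-smoothed ratio density on a fixed grid."""
    spread = np.ptp(theta)
    if spread == 0:
        return float(theta[0])
    sd = np.std(theta, ddof=1)
    iqr = np.subtract(*np.percentile(theta, [75, 25]))
    s = min(sd, iqr / 1.349) if iqr > 0 else sd
    hband = phi * 0.9 * s * len(theta) ** (-1 / 5)
    if hband <= 0:
        return float(np.median(theta))
    grid = np.linspace(theta.min() - 3 * hband, theta.max() + 3 * hband, n_grid)
    wn = w / np.sum(w)
    dens = np.sum(wn[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / hband) ** 2),
                  axis=0)
    return float(grid[np.argmax(dens)])


def mode_estimator(
    h: HarmonisedSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    n_grid: int = 512,
) -> MRResult:
    """Mode-based estimate: argmax of the kernel-smoothed density of the
    ratio estimates (uniform weights for the simple mode, inverse-variance
    weights for the weighted mode).  Bandwidth is ``phi`` times Silverman's
    rule on the ratios; SE by seeded parametric bootstrap."""
    theta, w = _ratio_arrays(h)
    if len(theta) < 3:
        raise EstimationError("mode estimator needs at least 3 usable variants")
    wu = w if weighted else np.ones_like(w)
    est = _mode_point(theta, wu, phi, n_grid)

    def point(bx, by, so):
        ok = bx != 0
        th = by[ok] / bx[ok]
        ww = (bx[ok] / so[ok]) ** 2 if weighted else np.ones(ok.sum())
        return _mode_point(th, ww, phi, n_grid)

    se = _bootstrap_se(h, point, n_boot, seed)
    method = "weighted-mode" if weighted else "simple-mode"
    res = _normal_result(method, est, se, h.n_variants)
    return res


def leave_one_out(h: HarmonisedSet, random_effects: bool = True) -> list[tuple[str, MRResult]]:
    """IVW re-estimated with each variant omitted in turn."""
    if h.n_variants < 3:
        raise EstimationError("leave-one-out needs at least 3 variants")
    out = []
    for vid in h.variant_ids:
        out.append((vid, ivw(h.drop_variant(vid), random_effects=random_effects)))
    return out


@dataclass
class UVMRSuiteResult:
    """Full univariate-MR output for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    eligible: bool
    n_instruments_preclump: int
    n_instruments: int
    harmonised: HarmonisedSet | None = None
    results: dict[str, MRResult] | None = None
    ivw_het: HeterogeneityStats | None = None
    egger_het: HeterogeneityStats | None = None
    i2gx: float | None = None
    loo: list[tuple[str, MRResult]] | None = None

    def table(self) -> pd.DataFrame:
        """Tidy results table, one row per estimator."""
        rows = []
        if self.results:
            intercept = self.results.get("egger-intercept")
            for method, r in self.results.items():
                if method == "egger-intercept":
                    continue
                het = self.ivw_het if method != "egger-slope" else self.egger_het
                rows.append({
                    "trait_id": self.exposure_id,
                    "outcome_id": self.outcome_id,
                    "method": method,
                    "n_variants": r.n_variants,
                    "estimate": r.estimate,
                    "se": r.se,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "pval": r.pval,
                    "q": het.q if het else np.nan,
                    "q_df": het.df if het else np.nan,
                    "q_pval": het.pval if het else np.nan,
                    "i2gx": self.i2gx if self.i2gx is not None else np.nan,
                    "egger_intercept": intercept.estimate if intercept else np.nan,
                    "egger_intercept_pval": intercept.pval if intercept else np.nan,
                })
        return pd.DataFrame(rows)


def run_uvmr_suite(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    ld: LDMatrix,
    config: MRConfig | None = None,
    sensitivity: bool = True,
) -> UVMRSuiteResult:
    """End-to-end univariate MR: instrument selection, LD clumping, the
    minimum-instrument gate, harmonisation, then IVW plus (optionally) the
    sensitivity estimators and diagnostics."""
    cfg = config or MRConfig()
    inst = select_instruments(exposure, cfg.p_threshold)
    pre = inst.n_variants
    clumped = greedy_clump(inst, ld, cfg.r2_threshold, cfg.window_bp)
    if not count_rule(clumped, cfg.min_instruments):
        log.info("%s -> %s: %d instruments after clumping (< %d), trait ineligible",
                 exposure.trait_id, outcome.trait_id, clumped.n_variants, cfg.min_instruments)
        return UVMRSuiteResult(exposure.trait_id, outcome.trait_id, False,
                               pre, clumped.n_variants)
    h = harmonise(clumped, outcome, cfg.palindrome_eaf_window)
    results: dict[str, MRResult] = {}
    res_ivw = ivw(h, cfg.random_effects)
    results["ivw"] = res_ivw
    ivw_het = cochran_q(h, res_ivw.estimate) if h.n_variants >= 2 else None
    egger_het = None
    i2 = i2gx(h) if h.n_variants >= 2 else None
    loo = None
    if sensitivity and h.n_variants >= 3:
        slope, intercept, egger_het = egger_regression(h, cfg.random_effects)
        results["egger-slope"] = slope
        results["egger-intercept"] = intercept
        results["weighted-median"] = weighted_median(h, cfg.n_boot, cfg.seed)
        results["simple-mode"] = mode_estimator(h, False, cfg.mode_phi, cfg.n_boot,
                                                cfg.seed + 1, cfg.mode_grid)
        results["weighted-mode"] = mode_estimator(h, True, cfg.mode_phi, cfg.n_boot,
                                                  cfg.seed + 2, cfg.mode_grid)
        loo = leave_one_out(h, cfg.random_effects)
    return UVMRSuiteResult(
        exposure.trait_id, outcome.trait_id, True, pre, h.n_variants,
        harmonised=h, results=results, ivw_het=ivw_het, egger_het=egger_het,
        i2gx=i2, loo=loo,
    )
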