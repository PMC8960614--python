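"""Multivariable Mendelian randomisation for (trait, mediator) -> outcome.

The direct effect of each exposure conditional on the other is the
coefficient of a no-intercept weighted regression of outcome betas on both
exposures' betas, weights 1/se_out^2.  Instrument strength is assessed per
exposure by a conditional F statistic and residual heterogeneity by a
modified Cochran's Q against its chi-squared 5% critical value.  Cross-trait
sampling covariance is taken as zero (non-overlapping GWAS samples); this is
a documented limitation where exposure and mediator cohorts overlap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EstimationError
from .sumstats_io import HarmonisedSet
from .uvmr import Z95

log = logging.getLogger(__name__)


@dataclass
class MVMRResult:
    """Direct (conditional) effects of the two exposures on the outcome."""

    exposure_ids: tuple[str, str]
    estimates: np.ndarray
    ses: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvals: np.ndarray
    n_variants: int

    @property
    def direct_trait(self) -> float:
        return float(self.estimates[0])

    @property
    def direct_mediator(self) -> float:
        return float(self.estimates[1])


@dataclass
class InstrumentStrength:
    """Conditional instrument strength and residual heterogeneity."""

    conditional_f: np.ndarray
    q_a: float
    q_a_df: int
    q_a_critical_5pct: float
    q_a_exceeds: bool


def _design(h: HarmonisedSet) -> np.ndarray:
    if not h.has_mediator:
        raise EstimationError("MVMR requires a three-way harmonised set with mediator columns")
    return np.column_stack([h.beta_exp, h.beta_med])


def mvmr_ivw(h: HarmonisedSet, random_effects: bool = True) -> MVMRResult:
    """Weighted no-intercept regression of outcome betas on both exposures'
    betas.  Coefficient SEs carry the same multiplicative random-effects
    floor as univariate IVW."""
    x = _design(h)
    k, n_exp = x.shape
    if k < n_exp + 1:
        raise EstimationError(f"MVMR needs at least {n_exp + 1} variants, got {k}")
    w = 1.0 / h.se_out**2
    # an identically-zero exposure column is excluded from the fit (nested
    # model); its coefficient and SE are reported as 0
    active = np.array([np.any(x[:, j] != 0) for j in range(n_exp)])
    xa = x[:, active]
    xs = xa * np.sqrt(w)[:, None]
    cond = np.linalg.cond(xs)
    if cond > 1e8:
        raise EstimationError(
            f"collinear exposures {h.exposure_id!r} and {h.mediator_id!r} "
            f"(condition number {cond:.3g})"
        )
    xtwx = xa.T @ (xa * w[:, None])
    coef_a = np.linalg.solve(xtwx, xa.T @ (w * h.beta_out))
    resid = h.beta_out - xa @ coef_a
    q_a = float(np.sum(w * resid**2))
    df = k - n_exp
    scale2 = max(1.0, q_a / df) if (random_effects and df > 0) else 1.0
    cov = scale2 * np.linalg.inv(xtwx)
    coef = np.zeros(n_exp)
    ses = np.zeros(n_exp)
    coef[active] = coef_a
    ses[active] = np.sqrt(np.diag(cov))
    z = np.divide(coef, ses, out=np.zeros_like(coef), where=ses > 0)
    pvals = np.maximum(2 * stats.norm.sf(np.abs(z)), 1e-300)
    return MVMRResult(
        exposure_ids=(h.exposure_id, h.mediator_id or "mediator"),
        estimates=coef, ses=ses,
        ci_low=coef - Z95 * ses, ci_high=coef + Z95 * ses,
        pvals=pvals, n_variants=k,
    )


def conditional_f(h: HarmonisedSet, exposure_index: int) -> float:
    """Conditional F statistic for one exposure given the other.

    The chosen exposure's instrument associations are regressed (without
    intercept) on the other exposure's, weighted by the chosen exposure's
    1/se^2 with cross-trait sampling covariance taken as 0; the statistic is
    the weighted residual sum of squares over (L - K + 1), L variants and
    K exposures.
    """
    x = _design(h)
    ses = np.column_stack([h.se_exp, h.se_med])
    L, K = x.shape
    if L < K + 1:
        raise EstimationError("too few variants for the conditional F statistic")
    y = x[:, exposure_index]
    z = np.delete(x, exposure_index, axis=1)
    v = 1.0 / ses[:, exposure_index] ** 2
    ztv = z.T @ (z * v[:, None])
    if np.linalg.cond(ztv) > 1e12:
        fitted = np.zeros(L)
    else:
        gamma = np.linalg.solve(ztv, z.T @ (v * y))
        fitted = z @ gamma
    q_x = float(np.sum(v * (y - fitted) ** 2))
    return q_x / (L - K + 1)


def modified_q(h: HarmonisedSet, fitted: MVMRResult) -> InstrumentStrength:
    """Modified Cochran's Q for MVMR residual heterogeneity.

    Q_A = sum_i w_i (beta_out_i - sum_j theta_j beta_x_ji)^2 with
    w = 1/se_out^2 and df = L - K, compared against the chi-squared 5%
    critical value.  The returned record also carries the per-exposure
    conditional F statistics.
    """
    x = _design(h)
    L, K = x.shape
    w = 1.0 / h.se_out**2
    resid = h.beta_out - x @ fitted.estimates
    q_a = float(np.sum(w * resid**2))
    df = max(L - K, 1)
    crit = float(stats.chi2.ppf(0.95, df))
    cf = np.array([conditional_f(h, j) for j in range(K)])
    return InstrumentStrength(
        conditional_f=cf, q_a=q_a, q_a_df=L - K,
        q_a_critical_5pct=crit, q_a_exceeds=bool(q_a > crit),
    )
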