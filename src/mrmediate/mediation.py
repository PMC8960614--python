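"""Two-step MR mediation: effect decomposition and the Egger attenuation bound.

The indirect (mediated) effect is the product of (i) the univariate MR
estimate of the trait's effect on the mediator and (ii) the mediator's
direct effect on the outcome from multivariable MR conditional on the
trait.  Its standard error uses the product-of-coefficients delta formula
with no covariance term (the two estimates come from separate fits):

    se(b1*b2) = sqrt(b2^2 se1^2 + b1^2 se2^2)

The proportion mediated is indirect/total with the total taken from the
univariate trait -> outcome MR.  Proportions outside [0, 1] are reported as
computed and flagged, never truncated.  The decomposition assumes linear
structural relations with no trait-by-mediator interaction; binary traits
stay on the log-odds scale throughout (non-collapsibility is addressed by
re-running with a linear-model mediator GWAS, not by rescaling).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .mvmr import MVMRResult
from .uvmr import MRResult, Z95


@dataclass
class MediationResult:
    """Total/direct/indirect effects and proportion mediated for one
    trait - mediator - outcome triple."""

    trait_id: str
    mediator_id: str
    outcome_id: str
    total: float
    total_se: float
    direct: float
    direct_se: float
    beta_trait_mediator: float
    beta_trait_mediator_se: float
    direct_mediator_outcome: float
    direct_mediator_outcome_se: float
    indirect: float
    indirect_se: float
    total_ci: tuple[float, float] = (math.nan, math.nan)
    direct_ci: tuple[float, float] = (math.nan, math.nan)
    indirect_ci: tuple[float, float] = (math.nan, math.nan)
    proportion_mediated: float = math.nan
    proportion_mediated_ci: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)


def decompose(
    total: MRResult,
    mvmr: MVMRResult,
    trait_to_mediator: MRResult,
    trait_id: str = "",
    mediator_id: str = "",
    outcome_id: str = "",
    proportion_ci: bool = False,
) -> MediationResult:
    """Two-step decomposition of the trait -> outcome effect.

    Parameters
    ----------
    total:
        Univariate MR estimate of the trait on the outcome.
    mvmr:
        Multivariable fit with exposures ordered (trait, mediator); its
        first coefficient is the direct effect, its second the mediator's
        direct effect on the outcome.
    trait_to_mediator:
        Univariate MR estimate of the trait on the mediator.
    proportion_ci:
        Also report a delta-method CI for the proportion mediated
        (off by default; the point estimate is the primary report).
    """
    b1, se1 = trait_to_mediator.estimate, trait_to_mediator.se
    b2, se2 = float(mvmr.estimates[1]), float(mvmr.ses[1])
    indirect = b1 * b2
    indirect_se = math.sqrt(b2**2 * se1**2 + b1**2 * se2**2)
    flags: list[str] = []
    if total.estimate != 0:
        prop = indirect / total.estimate
        if not 0 <= prop <= 1:
            flags.append("proportion_outside_unit_interval")
    else:
        prop = math.nan
        flags.append("total_effect_zero")

    prop_ci = None
    if proportion_ci and total.estimate != 0:
        # first-order delta method on the ratio, no covariance term
        rel2 = (indirect_se / indirect) ** 2 if indirect != 0 else 0.0
        rel2 += (total.se / total.estimate) ** 2
        prop_se = abs(prop) * math.sqrt(rel2)
        prop_ci = (prop - Z95 * prop_se, prop + Z95 * prop_se)

    return MediationResult(
        trait_id=trait_id or mvmr.exposure_ids[0],
        mediator_id=mediator_id or mvmr.exposure_ids[1],
        outcome_id=outcome_id,
        total=total.estimate, total_se=total.se,
        direct=float(mvmr.estimates[0]), direct_se=float(mvmr.ses[0]),
        beta_trait_mediator=b1, beta_trait_mediator_se=se1,
        direct_mediator_outcome=b2, direct_mediator_outcome_se=se2,
        indirect=indirect, indirect_se=indirect_se,
        total_ci=(total.estimate - Z95 * total.se, total.estimate + Z95 * total.se),
        direct_ci=(float(mvmr.ci_low[0]), float(mvmr.ci_high[0])),
        indirect_ci=(indirect - Z95 * indirect_se, indirect + Z95 * indirect_se),
        proportion_mediated=prop,
        proportion_mediated_ci=prop_ci,
        flags=flags,
    )


def egger_attenuation(i2gx: float) -> float:
    """Maximum relative attenuation (%) of the MR-Egger slope towards the
    null implied by measurement error in the exposure associations:
    (1 - I2_GX) * 100.  An I2_GX of 0.93 bounds the bias at 7%."""
    if not 0 <= i2gx <= 1:
        raise ValueError("I2_GX must lie in [0, 1]")
    return (1.0 - i2gx) * 100.0
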