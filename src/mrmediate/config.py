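"""Analysis configuration.

Defaults follow the conventions of large two-sample MR studies of
cardiometabolic disease: genome-wide significance p < 5e-8 for instrument
selection, LD clumping with r^2 < 0.001 inside a +/-10 Mb window, a minimum
of 10 variants per instrument, and a 5% Benjamini-Hochberg false discovery
rate for evidence screening.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

from .errors import ConfigurationError


@dataclass
class MRConfig:
    """Tunable parameters of the MR pipeline.

    Attributes
    ----------
    p_threshold:
        Instrument-selection p-value threshold (strict less-than).
    r2_threshold:
        Squared-correlation threshold for LD clumping.
    window_bp:
        Clump window in base pairs, interpreted as +/-``window_bp`` around
        each index variant (the convention of standard clumping tools).
    min_instruments:
        Instruments with fewer post-clump variants are removed.
    palindrome_eaf_window:
        Half-width w of the ambiguous allele-frequency zone [0.5-w, 0.5+w];
        palindromic variants with either frequency inside it are dropped.
    fdr_alpha:
        Benjamini-Hochberg false-discovery-rate level for "supportive"
        evidence (strict: adjusted p < alpha).
    fdr_scope:
        "family" corrects within each analysis family separately,
        "joint" pools all families into one correction.
    n_boot:
        Parametric-bootstrap replicates for median/mode standard errors.
    seed:
        Base seed for every stochastic component (bootstraps, simulation).
    random_effects:
        Multiplicative random-effects scaling of IVW/Egger/MVMR standard
        errors, floored at the fixed-effects value.
    mode_phi:
        Bandwidth multiplier for the mode estimators.
    mode_grid:
        Number of grid points for the mode density argmax.
    """

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_bp: int = 10_000_000
    min_instruments: int = 10
    palindrome_eaf_window: float = 0.08
    fdr_alpha: float = 0.05
    fdr_scope: str = "family"
    n_boot: int = 1000
    seed: int = 0
    random_effects: bool = True
    mode_phi: float = 1.0
    mode_grid: int = 512

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError("p_threshold must lie in (0, 1)")
        if self.fdr_scope not in ("family", "joint"):
            raise ConfigurationError("fdr_scope must be 'family' or 'joint'")
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be positive")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "MRConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in mapping.items() if k in known}
        return cls(**kwargs)
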