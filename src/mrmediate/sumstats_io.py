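"""Reading, validation and allele harmonisation of GWAS summary statistics.

Summary statistics are tab-separated text (gzip-transparent) with the
canonical columns ``variant_id, chromosome, position, effect_allele,
other_allele, eaf, beta, se, pval, n``.  Betas are per effect allele, in SD
units for continuous traits and log-odds for binary traits.

Harmonisation aligns an outcome (and optionally a mediator) GWAS to the
exposure GWAS variant by variant: swapped alleles flip the outcome beta and
complement its frequency, strand-complemented records are mapped back, and
palindromic variants (A/T, C/G) are resolved by effect-allele frequency or
dropped.  Finally every variant is oriented so that the effect allele
increases the exposure, the convention required by estimators that are not
invariant to allele coding (MR-Egger in particular).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

log = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL_COLUMNS = ("chromosome", "position", "eaf", "n")
CANONICAL_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROME_PAIRS = {"AT", "TA", "CG", "GC"}


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(_COMPLEMENT)


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return (ea + oa).isin(_PALINDROME_PAIRS)


@dataclass
class SummaryStatSet:
    """One GWAS: a validated table of per-variant associations."""

    trait_id: str
    df: pd.DataFrame
    trait_label: str = ""
    trait_type: str = "continuous"
    n_dropped_invalid: int = 0

    def __post_init__(self) -> None:
        if self.df["variant_id"].duplicated().any():
            dup = self.df["variant_id"].duplicated()
            log.warning(
                "%s: %d duplicated variant_ids, keeping first occurrence",
                self.trait_id, int(dup.sum()),
            )
            self.df = self.df[~dup].reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStatSet":
        ids = set(variant_ids)
        out = self.df[self.df["variant_id"].isin(ids)].reset_index(drop=True)
        return SummaryStatSet(self.trait_id, out, self.trait_label, self.trait_type)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _validate_frame(df: pd.DataFrame, trait_id: str) -> tuple[pd.DataFrame, int]:
    """Coerce types, enforce row invariants, return (valid rows, n dropped)."""
    df = df.copy()
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("beta", "se", "pval", "eaf", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["position"] = pd.to_numeric(df["position"], errors="coerce").fillna(0).astype(np.int64)
    df["chromosome"] = df["chromosome"].fillna("0").astype(str)
    df["variant_id"] = df["variant_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()

    valid_allele = df["effect_allele"].isin(_COMPLEMENT) & df["other_allele"].isin(_COMPLEMENT)
    ok = (
        valid_allele
        & (df["effect_allele"] != df["other_allele"])
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("%s: dropped %d rows failing record invariants", trait_id, n_dropped)
    return df[ok].reset_index(drop=True)[list(CANONICAL_COLUMNS)], n_dropped


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_label: str = "",
    trait_type: str = "continuous",
) -> SummaryStatSet:
    """Read one GWAS summary-statistics table.

    Parameters
    ----------
    path:
        Tab-separated text file (``.gz`` accepted).
    column_map:
        Mapping from canonical field name to the column name used in the
        file, e.g. ``{"beta": "b", "pval": "p"}``.  Unmapped canonical
        names are looked up directly.

    Rows violating record invariants (non-positive SE, p outside (0, 1],
    invalid alleles, frequency outside [0, 1]) are dropped and counted in
    ``n_dropped_invalid``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary statistics file not found: {path}")
    df = pd.read_csv(path, sep="\t", compression="infer", dtype=str)
    if column_map:
        rename = {file_col: std for std, file_col in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: cannot resolve mandatory column(s) {missing}; "
            f"available columns: {list(df.columns)}"
        )
    if df.empty:
        raise InputError(f"{path}: no data rows")
    frame, n_dropped = _validate_frame(df, trait_id or path.stem)
    return SummaryStatSet(
        trait_id=trait_id or path.stem,
        df=frame,
        trait_label=trait_label,
        trait_type=trait_type,
        n_dropped_invalid=n_dropped,
    )


def from_frame(
    trait_id: str,
    df: pd.DataFrame,
    trait_label: str = "",
    trait_type: str = "continuous",
) -> SummaryStatSet:
    """Build a validated SummaryStatSet from an in-memory frame."""
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"frame for {trait_id} lacks column(s) {missing}")
    frame, n_dropped = _validate_frame(df, trait_id)
    return SummaryStatSet(trait_id, frame, trait_label, trait_type, n_dropped)


def select_instruments(s: SummaryStatSet, p_threshold: float = 5e-8) -> SummaryStatSet:
    """Genome-wide-significant subset: pval strictly below the threshold."""
    if not 0 < p_threshold < 1:
        raise ConfigurationError("p_threshold must lie in (0, 1)")
    out = s.df[s.df["pval"] < p_threshold].reset_index(drop=True)
    return SummaryStatSet(s.trait_id, out, s.trait_label, s.trait_type)


@dataclass
class HarmonisedSet:
    """Per-variant aligned exposure (+ optional mediator) and outcome effects.

    Every variant is oriented to the exposure-increasing allele, so
    ``beta_exp >= 0`` throughout.
    """

    df: pd.DataFrame
    exposure_id: str = ""
    outcome_id: str = ""
    mediator_id: str | None = None
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0
    dropped_palindromic_ids: tuple[str, ...] = field(default_factory=tuple)
    dropped_incompatible_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_variants(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.df["variant_id"].to_numpy()

    @property
    def beta_exp(self) -> np.ndarray:
        return self.df["beta_exp"].to_numpy(float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.df["se_exp"].to_numpy(float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.df["beta_out"].to_numpy(float)

    @property
    def se_out(self) -> np.ndarray:
        return self.df["se_out"].to_numpy(float)

    @property
    def has_mediator(self) -> bool:
        return "beta_med" in self.df.columns

    @property
    def beta_med(self) -> np.ndarray:
        return self.df["beta_med"].to_numpy(float)

    @property
    def se_med(self) -> np.ndarray:
        return self.df["se_med"].to_numpy(float)

    def subset_mask(self, mask: np.ndarray) -> "HarmonisedSet":
        return HarmonisedSet(
            self.df[mask].reset_index(drop=True),
            self.exposure_id, self.outcome_id, self.mediator_id,
            self.n_dropped_palindromic, self.n_dropped_incompatible,
            self.dropped_palindromic_ids, self.dropped_incompatible_ids,
        )

    def drop_variant(self, variant_id: str) -> "HarmonisedSet":
        return self.subset_mask((self.df["variant_id"] != variant_id).to_numpy())

    def to_exposure_set(self) -> SummaryStatSet:
        cols = {
            "variant_id": self.df["variant_id"],
            "chromosome": self.df["chromosome"],
            "position": self.df["position"],
            "effect_allele": self.df["effect_allele"],
            "other_allele": self.df["other_allele"],
            "eaf": self.df["eaf_exp"],
            "beta": self.df["beta_exp"],
            "se": self.df["se_exp"],
            "pval": self.df["pval_exp"],
            "n": self.df["n_exp"],
        }
        return SummaryStatSet(self.exposure_id, pd.DataFrame(cols))

    def to_outcome_set(self) -> SummaryStatSet:
        cols = {
            "variant_id": self.df["variant_id"],
            "chromosome": self.df["chromosome"],
            "position": self.df["position"],
            "effect_allele": self.df["effect_allele"],
            "other_allele": self.df["other_allele"],
            "eaf": self.df["eaf_out"],
            "beta": self.df["beta_out"],
            "se": self.df["se_out"],
            "pval": self.df["pval_out"],
            "n": self.df["n_out"],
        }
        return SummaryStatSet(self.outcome_id, pd.DataFrame(cols))

    def write_tsv(self, path: str | Path) -> None:
        """TSV of the aligned table plus a JSON sidecar of drop counts."""
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        sidecar = {
            "exposure_id": self.exposure_id,
            "outcome_id": self.outcome_id,
            "mediator_id": self.mediator_id,
            "n_variants": self.n_variants,
            "n_dropped_palindromic": self.n_dropped_palindromic,
            "n_dropped_incompatible": self.n_dropped_incompatible,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def _align_pair(
    exposure: SummaryStatSet,
    other: SummaryStatSet,
    palindrome_eaf_window: float,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Align `other` to `exposure` alleles; no orientation yet.

    Returns the merged frame (other's beta/eaf already sign-corrected onto
    the exposure's allele labels) and the ids dropped as unresolvable
    palindromes / incompatible alleles.
    """
    if exposure.n_variants == 0 or other.n_variants == 0:
        raise InputError("cannot harmonise an empty summary-statistic set")
    m = exposure.df.merge(other.df, on="variant_id", suffixes=("_exp", "_out"))
    if m.empty:
        raise InputError(
            f"no overlapping variants between {exposure.trait_id} and {other.trait_id}"
        )
    ea_e, oa_e = m["effect_allele_exp"], m["other_allele_exp"]
    ea_o, oa_o = m["effect_allele_out"], m["other_allele_out"]
    cea_o, coa_o = _complement(ea_o), _complement(oa_o)

    pal = _is_palindromic(ea_e, oa_e).to_numpy()
    direct = ((ea_o == ea_e) & (oa_o == oa_e)).to_numpy()
    swapped = ((ea_o == oa_e) & (oa_o == ea_e)).to_numpy()
    flip_direct = ((cea_o == ea_e) & (coa_o == oa_e)).to_numpy()
    flip_swapped = ((cea_o == oa_e) & (coa_o == ea_e)).to_numpy()
    compatible = direct | swapped | flip_direct | flip_swapped

    # Palindromic variants: the four label comparisons above are ambiguous
    # (direct and flip_swapped coincide), so strand is resolved purely by
    # effect-allele frequency.
    w = palindrome_eaf_window
    eaf_e = m["eaf_exp"].to_numpy(float)
    eaf_o = m["eaf_out"].to_numpy(float)
    same_letters = (
        (ea_e + oa_e).map(lambda s: "".join(sorted(s)))
        == (ea_o + oa_o).map(lambda s: "".join(sorted(s)))
    ).to_numpy()
    eaf_resolvable = (
        ~np.isnan(eaf_e) & ~np.isnan(eaf_o)
        & (np.abs(eaf_e - 0.5) > w) & (np.abs(eaf_o - 0.5) > w)
    )
    same_side = (eaf_e > 0.5) == (eaf_o > 0.5)

    keep = np.where(pal, same_letters & eaf_resolvable, compatible)
    flip = np.where(pal, ~same_side, swapped | flip_swapped)

    pal_dropped = pal & same_letters & ~eaf_resolvable
    incompat = (~pal & ~compatible) | (pal & ~same_letters)

    out = m[keep].reset_index(drop=True)
    flip_kept = flip[keep]
    out.loc[flip_kept, "beta_out"] = -out.loc[flip_kept, "beta_out"]
    out.loc[flip_kept, "eaf_out"] = 1.0 - out.loc[flip_kept, "eaf_out"]
    out = out.drop(columns=["effect_allele_out", "other_allele_out",
                            "chromosome_out", "position_out"])
    out = out.rename(columns={
        "effect_allele_exp": "effect_allele", "other_allele_exp": "other_allele",
        "chromosome_exp": "chromosome", "position_exp": "position",
    })
    return (
        out,
        list(m.loc[pal_dropped, "variant_id"]),
        list(m.loc[incompat, "variant_id"]),
    )


def _orient_to_exposure(df: pd.DataFrame, med: bool = False) -> pd.DataFrame:
    """Flip every variant with negative exposure beta so beta_exp >= 0."""
    neg = (df["beta_exp"] < 0).to_numpy()
    if not neg.any():
        return df
    df = df.copy()
    ea = df.loc[neg, "effect_allele"].copy()
    df.loc[neg, "effect_allele"] = df.loc[neg, "other_allele"].to_numpy()
    df.loc[neg, "other_allele"] = ea.to_numpy()
    for col in ("beta_exp", "beta_out") + (("beta_med",) if med else ()):
        df.loc[neg, col] = -df.loc[neg, col]
    for col in ("eaf_exp", "eaf_out") + (("eaf_med",) if med else ()):
        if col in df.columns:
            df.loc[neg, col] = 1.0 - df.loc[neg, col]
    return df


def harmonise(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    palindrome_eaf_window: float = 0.08,
) -> HarmonisedSet:
    """Two-way harmonisation of outcome onto exposure, oriented so that
    each variant's effect allele increases the exposure."""
    aligned, pal_ids, incompat_ids = _align_pair(exposure, outcome, palindrome_eaf_window)
    aligned = _orient_to_exposure(aligned)
    return HarmonisedSet(
        df=aligned,
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        n_dropped_palindromic=len(pal_ids),
        n_dropped_incompatible=len(incompat_ids),
        dropped_palindromic_ids=tuple(pal_ids),
        dropped_incompatible_ids=tuple(incompat_ids),
    )


def merge_for_mvmr(
    exposure: SummaryStatSet,
    mediator: SummaryStatSet,
    outcome: SummaryStatSet,
    instruments: Sequence[str],
    palindrome_eaf_window: float = 0.08,
) -> HarmonisedSet:
    """Three-way harmonisation on a given instrument list.

    ``instruments`` is the (clumped) union of the exposure's and mediator's
    instruments.  Variants missing from any of the three sets, unresolvable
    palindromes and allele-incompatible records are dropped and counted.
    """
    requested = list(dict.fromkeys(instruments))
    exp_sub = exposure.subset(requested)
    if exp_sub.n_variants == 0:
        raise InputError("none of the requested instruments found in the exposure set")

    hm, pal_m, inc_m = _align_pair(exp_sub, mediator, palindrome_eaf_window)
    hm = hm.rename(columns={c: c.replace("_out", "_med") for c in hm.columns if c.endswith("_out")})
    ho, pal_o, inc_o = _align_pair(exp_sub, outcome, palindrome_eaf_window)

    med_cols = hm[["variant_id", "eaf_med", "beta_med", "se_med", "pval_med", "n_med"]]
    merged = ho.merge(med_cols, on="variant_id", how="inner")
    merged = _orient_to_exposure(merged, med=True)

    retained = set(merged["variant_id"])
    pal_ids = (set(pal_m) | set(pal_o)) - retained
    incompat_ids = set(requested) - retained - pal_ids
    if len(merged) < 3:
        log.warning(
            "MVMR merge for %s/%s/%s retains only %d variants (< exposures + 1)",
            exposure.trait_id, mediator.trait_id, outcome.trait_id, len(merged),
        )
    return HarmonisedSet(
        df=merged,
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        mediator_id=mediator.trait_id,
        n_dropped_palindromic=len(pal_ids),
        n_dropped_incompatible=len(incompat_ids),
        dropped_palindromic_ids=tuple(sorted(pal_ids)),
        dropped_incompatible_ids=tuple(sorted(incompat_ids)),
    )
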