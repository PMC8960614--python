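"""Two-stage study orchestration: evidence screening and mediation.

Stage 1 runs bidirectional univariate MR between every trait and the
mediator plus univariate MR of every trait on each outcome, then classifies
evidence with a Benjamini-Hochberg false discovery rate of 5% per analysis
family.  A trait progresses to stage 2 for an outcome when (1) it shows
supportive evidence of an effect on the mediator, (2) only limited evidence
of the reverse effect (bidirectional traits are excluded because exposure
and mediator cannot be told apart), and (3) supportive evidence of an
effect on that outcome.  Stage 2 runs multivariable MR of (trait, mediator)
on the outcome and the two-step mediation decomposition.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from .config import MRConfig
from .errors import ConfigurationError, InputError
from .ld_clump import LDMatrix, greedy_clump
from .mediation import MediationResult, decompose
from .mvmr import mvmr_ivw, modified_q
from .sumstats_io import (SummaryStatSet, harmonise, merge_for_mvmr,
                          read_sumstats, select_instruments)
from .uvmr import UVMRSuiteResult, run_uvmr_suite

log = logging.getLogger(__name__)

FAMILY_FORWARD = "trait->mediator"
FAMILY_REVERSE = "mediator->trait"


def family_outcome(outcome_id: str) -> str:
    return f"trait->{outcome_id}"


def bh_fdr(pvals: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (adjusted p-values, reject flags); rejection is strict
    (adjusted p < alpha).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, adjusted < alpha


def classify_bidirectional(forward_supportive: bool, reverse_supportive: bool) -> str:
    """Truth-table classification of the trait-mediator relationship."""
    if forward_supportive and reverse_supportive:
        return "bidirectional"
    if forward_supportive:
        return "cause-only"
    if reverse_supportive:
        return "consequence-only"
    return "neither"


@dataclass
class StageDecision:
    """Stage-2 eligibility of one trait, per outcome."""

    trait_id: str
    cause_of_mediator: bool
    consequence_of_mediator: bool
    bidirectional: bool
    stage2: dict[str, bool] = field(default_factory=dict)
    status: str = "ok"  # ok | ineligible-instruments

    def as_row(self) -> dict:
        row = {
            "trait_id": self.trait_id,
            "cause_of_mediator": self.cause_of_mediator,
            "consequence_of_mediator": self.consequence_of_mediator,
            "bidirectional": self.bidirectional,
            "status": self.status,
        }
        for o, flag in self.stage2.items():
            row[f"stage2_{o}"] = flag
        return row


def stage2_eligibility(
    evidence: pd.DataFrame, trait_id: str, outcome_ids: Sequence[str]
) -> StageDecision:
    """Apply the three-condition progression rule for one trait.

    ``evidence`` must carry one row per (trait_id, family) with a
    ``supportive`` flag; a missing family row is an error.
    """
    sub = evidence[evidence["trait_id"] == trait_id].set_index("family")
    needed = [FAMILY_FORWARD, FAMILY_REVERSE] + [family_outcome(o) for o in outcome_ids]
    missing = [f for f in needed if f not in sub.index]
    if missing:
        raise InputError(f"incomplete evidence for {trait_id}: missing {missing}")
    fwd = bool(sub.loc[FAMILY_FORWARD, "supportive"])
    rev = bool(sub.loc[FAMILY_REVERSE, "supportive"])
    category = classify_bidirectional(fwd, rev)
    eligible_base = category == "cause-only"
    stage2 = {
        o: bool(eligible_base and sub.loc[family_outcome(o), "supportive"])
        for o in outcome_ids
    }
    status = "ok" if bool(sub["eligible"].all()) else "ineligible-instruments"
    return StageDecision(trait_id, fwd, rev, category == "bidirectional", stage2, status)


@dataclass
class StudyInputs:
    """In-memory inputs of a full two-stage study."""

    traits: Mapping[str, SummaryStatSet]
    mediator: SummaryStatSet
    outcomes: Mapping[str, SummaryStatSet]
    ld: LDMatrix


@dataclass
class StudyResult:
    evidence: pd.DataFrame
    decisions: list[StageDecision]
    mvmr_table: pd.DataFrame
    mediation_table: pd.DataFrame
    mediation_results: list[MediationResult]
    manifest: dict

    def decisions_table(self) -> pd.DataFrame:
        return pd.DataFrame([d.as_row() for d in self.decisions])


def _mvmr_instruments(
    trait: SummaryStatSet,
    mediator: SummaryStatSet,
    ld: LDMatrix,
    cfg: MRConfig,
) -> list[str]:
    """Union of both exposures' genome-wide-significant variants, clumped
    using the p-values of the exposure with the smaller instrument."""
    inst_t = select_instruments(trait, cfg.p_threshold)
    inst_m = select_instruments(mediator, cfg.p_threshold)
    ref, other = (inst_t, inst_m) if inst_t.n_variants <= inst_m.n_variants else (inst_m, inst_t)
    union_ids = list(dict.fromkeys(list(ref.df["variant_id"]) + list(other.df["variant_id"])))
    # p-values (and coordinates) from the reference exposure's full GWAS
    # where available, the other exposure otherwise
    ref_full = trait if ref.trait_id == trait.trait_id else mediator
    other_full = mediator if ref.trait_id == trait.trait_id else trait
    ref_rows = ref_full.df.set_index("variant_id")
    other_rows = other_full.df.set_index("variant_id")
    rows = []
    for vid in union_ids:
        if vid in ref_rows.index:
            rows.append(ref_rows.loc[vid])
        elif vid in other_rows.index:
            rows.append(other_rows.loc[vid])
    combined = pd.DataFrame(rows).reset_index(names="variant_id")
    clumped = greedy_clump(
        SummaryStatSet("mvmr-union", combined), ld, cfg.r2_threshold, cfg.window_bp
    )
    return list(clumped.df["variant_id"])


def run_triple(
    trait: SummaryStatSet,
    mediator: SummaryStatSet,
    outcome: SummaryStatSet,
    ld: LDMatrix,
    config: MRConfig | None = None,
) -> MediationResult:
    """Two-step mediation analysis for a single trait-mediator-outcome
    triple, bypassing the stage-1 evidence screen: univariate MR for the
    total and trait-on-mediator effects, multivariable MR for the direct
    effects, then the product-of-coefficients decomposition."""
    cfg = config or MRConfig()
    total_suite = run_uvmr_suite(trait, outcome, ld, cfg, sensitivity=False)
    t2m_suite = run_uvmr_suite(trait, mediator, ld, cfg, sensitivity=False)
    if not (total_suite.eligible and t2m_suite.eligible):
        raise InputError(f"{trait.trait_id}: instrument fails the minimum-variant rule")
    inst = _mvmr_instruments(trait, mediator, ld, cfg)
    h3 = merge_for_mvmr(trait, mediator, outcome, inst, cfg.palindrome_eaf_window)
    fit = mvmr_ivw(h3, cfg.random_effects)
    return decompose(total_suite.results["ivw"], fit, t2m_suite.results["ivw"],
                     trait.trait_id, mediator.trait_id, outcome.trait_id)


def run_study_inputs(
    inputs: StudyInputs,
    config: MRConfig | None = None,
    out_dir: str | Path | None = None,
    sensitivity: bool = True,
) -> StudyResult:
    """Run the full two-stage design on in-memory inputs.

    Per-trait failures are recorded in the manifest rather than aborting
    the run.  With ``out_dir`` set, writes stage1_evidence.tsv,
    stage_decisions.tsv, mvmr_results.tsv, mediation_results.tsv and
    run_manifest.json.
    """
    cfg = config or MRConfig()
    outcome_ids = list(inputs.outcomes)
    warnings: list[str] = []
    suites: dict[tuple[str, str], UVMRSuiteResult] = {}

    evid_rows = []
    for trait_id in inputs.traits:
        trait = inputs.traits[trait_id]
        analyses = [
            (FAMILY_FORWARD, trait, inputs.mediator),
            (FAMILY_REVERSE, inputs.mediator, trait),
        ] + [(family_outcome(o), trait, inputs.outcomes[o]) for o in outcome_ids]
        for fam, exp, outc in analyses:
            try:
                suite = run_uvmr_suite(exp, outc, inputs.ld, cfg, sensitivity=sensitivity)
            except Exception as exc:  # recorded, not fatal
                warnings.append(f"{trait_id}/{fam}: {exc}")
                log.warning("%s/%s failed: %s", trait_id, fam, exc)
                suite = UVMRSuiteResult(exp.trait_id, outc.trait_id, False, 0, 0)
            suites[(trait_id, fam)] = suite
            r = suite.results.get("ivw") if suite.results else None
            evid_rows.append({
                "trait_id": trait_id,
                "family": fam,
                "eligible": suite.eligible,
                "n_variants": suite.n_instruments,
                "estimate": r.estimate if r else np.nan,
                "se": r.se if r else np.nan,
                "pval": r.pval if r else np.nan,
            })
    evidence = pd.DataFrame(evid_rows)

    # FDR within each analysis family (or jointly), over eligible rows only
    evidence["fdr_adjusted_pval"] = np.nan
    evidence["supportive"] = False
    groups = [evidence.index[evidence["family"] == f]
              for f in evidence["family"].unique()] if cfg.fdr_scope == "family" \
        else [evidence.index]
    for idx in groups:
        ok = idx[evidence.loc[idx, "pval"].notna()]
        if len(ok) == 0:
            continue
        adj, rej = bh_fdr(evidence.loc[ok, "pval"].to_numpy(), cfg.fdr_alpha)
        evidence.loc[ok, "fdr_adjusted_pval"] = adj
        evidence.loc[ok, "supportive"] = rej

    decisions = [stage2_eligibility(evidence, t, outcome_ids) for t in inputs.traits]

    mvmr_rows, med_rows, med_results = [], [], []
    for dec in decisions:
        trait = inputs.traits[dec.trait_id]
        for o, go in dec.stage2.items():
            if not go:
                continue
            try:
                inst = _mvmr_instruments(trait, inputs.mediator, inputs.ld, cfg)
                h3 = merge_for_mvmr(trait, inputs.mediator, inputs.outcomes[o],
                                    inst, cfg.palindrome_eaf_window)
                fit = mvmr_ivw(h3, cfg.random_effects)
                strength = modified_q(h3, fit)
                total = suites[(dec.trait_id, family_outcome(o))].results["ivw"]
                t2m = suites[(dec.trait_id, FAMILY_FORWARD)].results["ivw"]
                med = decompose(total, fit, t2m, dec.trait_id,
                                inputs.mediator.trait_id, o)
            except Exception as exc:
                warnings.append(f"stage2 {dec.trait_id}/{o}: {exc}")
                log.warning("stage2 %s/%s failed: %s", dec.trait_id, o, exc)
                continue
            mvmr_rows.append({
                "trait_id": dec.trait_id, "mediator_id": inputs.mediator.trait_id,
                "outcome_id": o, "n_variants": fit.n_variants,
                "direct_trait": fit.estimates[0], "direct_trait_se": fit.ses[0],
                "direct_trait_ci_low": fit.ci_low[0], "direct_trait_ci_high": fit.ci_high[0],
                "direct_trait_pval": fit.pvals[0],
                "direct_mediator": fit.estimates[1], "direct_mediator_se": fit.ses[1],
                "direct_mediator_ci_low": fit.ci_low[1],
                "direct_mediator_ci_high": fit.ci_high[1],
                "direct_mediator_pval": fit.pvals[1],
                "f_trait": strength.conditional_f[0],
                "f_mediator": strength.conditional_f[1],
                "q_a": strength.q_a, "q_a_df": strength.q_a_df,
                "q_a_exceeds": strength.q_a_exceeds,
            })
            med_results.append(med)
            med_rows.append({
                "trait_id": med.trait_id, "mediator_id": med.mediator_id,
                "outcome_id": med.outcome_id,
                "total": med.total, "total_se": med.total_se,
                "total_ci_low": med.total_ci[0], "total_ci_high": med.total_ci[1],
                "direct": med.direct, "direct_se": med.direct_se,
                "direct_ci_low": med.direct_ci[0], "direct_ci_high": med.direct_ci[1],
                "indirect": med.indirect, "indirect_se": med.indirect_se,
                "indirect_ci_low": med.indirect_ci[0],
                "indirect_ci_high": med.indirect_ci[1],
                "proportion_mediated": med.proportion_mediated,
                "flags": ";".join(med.flags),
            })

    mvmr_table = pd.DataFrame(mvmr_rows)
    mediation_table = pd.DataFrame(med_rows)
    manifest = {
        "software": {"name": "mrmediate", "version": __version__},
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "n_traits": len(inputs.traits),
        "outcomes": outcome_ids,
        "row_counts": {
            "stage1_evidence": len(evidence),
            "stage_decisions": len(decisions),
            "mvmr_results": len(mvmr_table),
            "mediation_results": len(mediation_table),
        },
        "conventions": {
            "clump_window": "window_bp interpreted as +/- window around the index variant",
            "mvmr_clump_reference": "p-values of the exposure with the smaller instrument",
            "conditional_f": "Q_x / (L - K + 1), cross-trait sampling covariance 0",
            "egger_inference": "t distribution with k-2 df",
            "total_effect": "univariate IVW of trait on outcome",
            "fdr_scope": cfg.fdr_scope,
        },
        "warnings": warnings,
    }
    result = StudyResult(evidence, decisions, mvmr_table, mediation_table,
                         med_results, manifest)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {
        "stage1_evidence.tsv": result.evidence,
        "stage_decisions.tsv": result.decisions_table(),
        "mvmr_results.tsv": result.mvmr_table,
        "mediation_results.tsv": result.mediation_table,
    }
    for name, df in files.items():
        df.to_csv(out_dir / name, sep="\t", index=False, float_format="%.10g")
    result.manifest["files"] = {
        name: _sha256(out_dir / name) for name in files
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(result.manifest, indent=1))


@dataclass
class StudyConfig:
    """File-based study configuration (YAML-friendly)."""

    trait_files: dict[str, str]
    mediator_file: str
    outcome_files: dict[str, str]
    ld_matrix: str
    ld_format: str = "square"  # square | long
    out_dir: str = "results"
    mr: MRConfig = field(default_factory=MRConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        for key in ("trait_files", "mediator_file", "outcome_files", "ld_matrix"):
            if key not in raw:
                raise ConfigurationError(f"{path}: missing required key {key!r}")
        mr = MRConfig.from_mapping(raw)
        return cls(
            trait_files=dict(raw["trait_files"]),
            mediator_file=raw["mediator_file"],
            outcome_files=dict(raw["outcome_files"]),
            ld_matrix=raw["ld_matrix"],
            ld_format=raw.get("ld_format", "square"),
            out_dir=raw.get("out_dir", "results"),
            mr=mr,
        )


def run_study(config: StudyConfig, sensitivity: bool = True) -> StudyResult:
    """Load the files named in ``config`` and run the full study."""
    traits = {tid: read_sumstats(p, trait_id=tid) for tid, p in config.trait_files.items()}
    mediator = read_sumstats(config.mediator_file, trait_id=Path(config.mediator_file).stem)
    outcomes = {oid: read_sumstats(p, trait_id=oid) for oid, p in config.outcome_files.items()}
    ld = (LDMatrix.from_square_tsv(config.ld_matrix) if config.ld_format == "square"
          else LDMatrix.from_long_tsv(config.ld_matrix))
    inputs = StudyInputs(traits, mediator, outcomes, ld)
    return run_study_inputs(inputs, config.mr, out_dir=config.out_dir,
                            sensitivity=sensitivity)
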