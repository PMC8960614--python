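"""Seeded generator of three-sample GWAS summary statistics.

Emulates the inputs of a two-step MR mediation study: an exposure trait X,
a mediator M (liability to disease, e.g. type 2 diabetes) and an outcome Y
(liability to atherosclerotic disease), measured in three non-overlapping
GWAS samples.  The structural system is linear:

    M = beta_XM * X + delta . G_M          (mediator's own instruments G_M)
    Y = theta_X * X + theta_M * M + alpha . G_X   (pleiotropy alpha)

so a trait instrument with effect gamma on X has true association
beta_XM*gamma with M and theta_X*gamma + theta_M*beta_XM*gamma + alpha
with Y; the implied total effect of X on Y is theta_X + beta_XM*theta_M.

Summary statistics are simulated directly at the summary level: the
observed beta in each GWAS is the true association plus Gaussian noise
with standard error 1/sqrt(n * 2f(1-f)), the standard approximation for a
standardised phenotype.  Allele labels, frequencies, palindromic variants,
swapped-allele and strand-flipped records are injected so harmonisation is
exercised end to end.  LD is emulated with exchangeable blocks: one causal
variant per block plus tags whose associations (with every phenotype) are
rho times the causal variant's, matching a within-block correlation rho.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ld_clump import LDMatrix
from .sumstats_io import SummaryStatSet

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# non-strand-ambiguous allele pairs
_NONPAL_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Parameters of the simulated trait -> mediator -> outcome system.

    Sample sizes default to the scale of large consortium GWAS
    (hundreds of thousands); per-allele effects are drawn uniformly on
    [gamma_min, gamma_max] with random sign, large enough to reach genome-
    wide significance at those sample sizes.
    """

    n_snps_trait: int = 100
    n_snps_mediator: int = 100
    n_trait: int = 200_000
    n_mediator_gwas: int = 200_000
    n_outcome_gwas: int = 180_000
    theta_X: float = 0.2
    beta_XM: float = 0.3
    theta_M: float = 0.5
    reverse_MX: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    invalid_fraction: float = 0.0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    palindromic_rate: float = 0.10
    swap_allele_rate: float = 0.30
    strand_flip_rate: float = 0.10
    gamma_min: float = 0.04
    gamma_max: float = 0.10
    eaf_min: float = 0.05
    eaf_max: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        assert self.n_trait > 0 and self.n_mediator_gwas > 0 and self.n_outcome_gwas > 0
        assert 0 <= self.invalid_fraction <= 1
        assert abs(self.ld_rho) < 1
        assert self.pleiotropy_mode in ("none", "balanced", "directional")


@dataclass
class TruthRecord:
    """Ground truth of one simulated study, for parameter-recovery tests."""

    theta_X: float
    beta_XM: float
    theta_M: float
    reverse_MX: float
    gamma: np.ndarray  # causal trait-instrument effects on X
    delta: np.ndarray  # mediator's own instrument effects on M
    alpha: np.ndarray  # pleiotropic effects on Y at trait instruments

    @property
    def implied_total(self) -> float:
        return self.theta_X + self.beta_XM * self.theta_M

    @property
    def implied_indirect(self) -> float:
        return self.beta_XM * self.theta_M

    @property
    def implied_proportion_mediated(self) -> float:
        return self.implied_indirect / self.implied_total

    def to_json(self, path: str | Path) -> None:
        d = {
            "theta_X": self.theta_X, "beta_XM": self.beta_XM,
            "theta_M": self.theta_M, "reverse_MX": self.reverse_MX,
            "gamma": list(self.gamma), "delta": list(self.delta),
            "alpha": list(self.alpha),
            "implied_total": self.implied_total,
            "implied_proportion_mediated": self.implied_proportion_mediated,
        }
        Path(path).write_text(json.dumps(d, indent=1))


def _layout(n_blocks: int, block_size: int, start_block: int = 0):
    """Chromosome/position layout: blocks 20 Mb apart (farther than the
    standard clump window), tags 10 kb apart within a block."""
    chroms, poss = [], []
    for b in range(n_blocks):
        g = start_block + b
        chrom = str(g % 22 + 1)
        base = 1_000_000 + (g // 22) * 20_000_000
        for t in range(block_size):
            chroms.append(chrom)
            poss.append(base + t * 10_000)
    return np.array(chroms), np.array(poss, dtype=np.int64)


def _alleles(rng: np.random.Generator, n: int, palindromic_rate: float):
    pal = rng.random(n) < palindromic_rate
    ea = np.empty(n, dtype="<U1")
    oa = np.empty(n, dtype="<U1")
    pal_idx = rng.integers(0, len(_PAL_PAIRS), size=n)
    non_idx = rng.integers(0, len(_NONPAL_PAIRS), size=n)
    for i in range(n):
        ea[i], oa[i] = _PAL_PAIRS[pal_idx[i]] if pal[i] else _NONPAL_PAIRS[non_idx[i]]
    return ea, oa


def _observe(
    rng: np.random.Generator,
    true_beta: np.ndarray,
    eaf: np.ndarray,
    n_sample: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed (beta, se, pval) for one GWAS sample."""
    from scipy import stats

    se = 1.0 / np.sqrt(n_sample * 2.0 * eaf * (1.0 - eaf))
    beta = true_beta + rng.normal(0.0, se)
    pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return beta, se, pval


def _scramble(
    rng: np.random.Generator,
    df: pd.DataFrame,
    swap_rate: float,
    flip_rate: float,
) -> pd.DataFrame:
    """Re-express some records on the other allele and/or other strand, as
    real GWAS files do; the information content is unchanged."""
    df = df.copy()
    n = len(df)
    swap = rng.random(n) < swap_rate
    flip = rng.random(n) < flip_rate
    ea = df["effect_allele"].to_numpy().copy()
    oa = df["other_allele"].to_numpy().copy()
    beta = df["beta"].to_numpy().copy()
    eaf = df["eaf"].to_numpy().copy()
    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    beta[swap] = -beta[swap]
    eaf[swap] = 1.0 - eaf[swap]
    if flip.any():
        ea[flip] = [_COMPLEMENT[a] for a in ea[flip]]
        oa[flip] = [_COMPLEMENT[a] for a in oa[flip]]
    df["effect_allele"], df["other_allele"] = ea, oa
    df["beta"], df["eaf"] = beta, eaf
    return df


def _frame(ids, chrom, pos, ea, oa, eaf, beta, se, pval, n) -> pd.DataFrame:
    return pd.DataFrame({
        "variant_id": ids, "chromosome": chrom, "position": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": pval, "n": n,
    })


def simulate_study(
    cfg: SimulationConfig,
) -> tuple[SummaryStatSet, SummaryStatSet, SummaryStatSet, LDMatrix, TruthRecord]:
    """Generate (trait, mediator, outcome) summary statistics, the LD
    matrix of the simulated variants, and the ground-truth record."""
    rng = np.random.default_rng(cfg.seed)
    bs = max(1, cfg.ld_block_size)
    n_t, n_m = cfg.n_snps_trait, cfg.n_snps_mediator
    n_blocks = n_t + n_m

    # causal effects
    gamma = rng.uniform(cfg.gamma_min, cfg.gamma_max, n_t) * rng.choice([-1.0, 1.0], n_t)
    delta = rng.uniform(cfg.gamma_min, cfg.gamma_max, n_m) * rng.choice([-1.0, 1.0], n_m)
    alpha = np.zeros(n_t)
    if cfg.pleiotropy_mode != "none":
        n_invalid = int(round(cfg.invalid_fraction * n_t))
        which = rng.choice(n_t, size=n_invalid, replace=False)
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        alpha[which] = rng.normal(mean, cfg.pleiotropy_sd, n_invalid)

    # causal-level true associations
    causal_x = np.concatenate([gamma, cfg.reverse_MX * delta])
    causal_m = np.concatenate([cfg.beta_XM * gamma, delta])
    causal_y = cfg.theta_X * causal_x + cfg.theta_M * causal_m
    causal_y[:n_t] += alpha

    # expand blocks: causal variant first, tags at rho * causal association
    reps = np.repeat(np.arange(n_blocks), bs)
    tag_factor = np.where(np.arange(n_blocks * bs) % bs == 0, 1.0, cfg.ld_rho)
    true_x = causal_x[reps] * tag_factor
    true_m = causal_m[reps] * tag_factor
    true_y = causal_y[reps] * tag_factor

    n_all = n_blocks * bs
    ids = np.array([
        (f"trait_snp{b}" if b < n_t else f"med_snp{b - n_t}") + ("" if t == 0 else f"_tag{t}")
        for b in range(n_blocks) for t in range(bs)
    ])
    chrom, pos = _layout(n_blocks, bs)
    eaf = rng.uniform(cfg.eaf_min, cfg.eaf_max, n_all)
    ea, oa = _alleles(rng, n_all, cfg.palindromic_rate)

    bx, sx, px = _observe(rng, true_x, eaf, cfg.n_trait)
    bm, sm, pm = _observe(rng, true_m, eaf, cfg.n_mediator_gwas)
    by, sy, py = _observe(rng, true_y, eaf, cfg.n_outcome_gwas)

    trait_df = _frame(ids, chrom, pos, ea, oa, eaf, bx, sx, px, cfg.n_trait)
    med_df = _scramble(rng, _frame(ids, chrom, pos, ea, oa, eaf, bm, sm, pm,
                                   cfg.n_mediator_gwas),
                       cfg.swap_allele_rate, cfg.strand_flip_rate)
    out_df = _scramble(rng, _frame(ids, chrom, pos, ea, oa, eaf, by, sy, py,
                                   cfg.n_outcome_gwas),
                       cfg.swap_allele_rate, cfg.strand_flip_rate)

    if bs > 1 and cfg.ld_rho != 0.0:
        r = np.kron(np.eye(n_blocks),
                    np.full((bs, bs), cfg.ld_rho) + (1 - cfg.ld_rho) * np.eye(bs))
    else:
        r = np.eye(n_all)
    ld = LDMatrix(list(ids), r)

    truth = TruthRecord(cfg.theta_X, cfg.beta_XM, cfg.theta_M, cfg.reverse_MX,
                        gamma, delta, alpha)
    return (
        SummaryStatSet("trait", trait_df, trait_label="simulated trait"),
        SummaryStatSet("t2d", med_df, trait_label="simulated mediator",
                       trait_type="binary-logistic"),
        SummaryStatSet("outcome", out_df, trait_label="simulated outcome",
                       trait_type="binary-logistic"),
        ld,
        truth,
    )


def make_bidirectional_fixture(
    cfg: SimulationConfig,
) -> tuple[SummaryStatSet, SummaryStatSet, SummaryStatSet, LDMatrix, TruthRecord]:
    """Study inputs where trait and mediator cause each other: the
    mediator's instruments also perturb the trait, so both MR directions
    come out supportive at scale."""
    if cfg.reverse_MX == 0:
        raise ValueError("bidirectional fixture requires reverse_MX != 0")
    return simulate_study(cfg)


def write_fixture(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write fixture TSVs, the LD matrix and the truth JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trait, med, outc, ld, truth = simulate_study(cfg)
    paths = {
        "trait": out / "trait.tsv",
        "mediator": out / "mediator.tsv",
        "outcome": out / "outcome.tsv",
        "ld": out / "ld_matrix.tsv",
        "truth": out / "truth.json",
        "config": out / "sim_config.json",
    }
    trait.write_tsv(paths["trait"])
    med.write_tsv(paths["mediator"])
    outc.write_tsv(paths["outcome"])
    ld.write_square_tsv(paths["ld"])
    truth.to_json(paths["truth"])
    paths["config"].write_text(json.dumps(asdict(cfg), indent=1))
    return paths


# ---------------------------------------------------------------------------
# multi-trait screening studies


@dataclass
class TraitSpec:
    """One trait in a multi-trait screening study."""

    trait_id: str
    n_snps: int = 30
    beta_to_mediator: float = 0.0   # causal effect of the trait on the mediator
    reverse_from_mediator: float = 0.0  # causal effect of the mediator on the trait
    theta_outcomes: dict[str, float] = field(default_factory=dict)  # direct effects


@dataclass
class ScreeningStudy:
    """Inputs plus construction metadata for a multi-trait study."""

    traits: dict[str, SummaryStatSet]
    mediator: SummaryStatSet
    outcomes: dict[str, SummaryStatSet]
    ld: LDMatrix
    truth: dict


def simulate_screening_study(
    trait_specs: list[TraitSpec],
    outcome_ids: tuple[str, ...] = ("cad", "pad"),
    theta_M: dict[str, float] | None = None,
    n_snps_mediator: int = 30,
    n_trait: int = 200_000,
    n_mediator_gwas: int = 50_000,
    n_outcome_gwas: int = 200_000,
    gamma_range: tuple[float, float] = (0.05, 0.09),
    delta_range: tuple[float, float] = (0.10, 0.16),
    eaf_range: tuple[float, float] = (0.05, 0.95),
    palindromic_rate: float = 0.05,
    seed: int = 0,
) -> ScreeningStudy:
    """Simulate a full stage-1/stage-2 study over several traits sharing
    one mediator and one GWAS per outcome.

    Effect scales are separated so that trait instruments stay below
    genome-wide significance in the mediator GWAS (and vice versa), keeping
    each trait's instrument set disjoint from the mediator's.
    """
    from scipy import stats  # noqa: F401  (via _observe)

    rng = np.random.default_rng(seed)
    theta_M = theta_M or {o: 0.5 for o in outcome_ids}

    delta = rng.uniform(*delta_range, n_snps_mediator) * rng.choice([-1.0, 1.0], n_snps_mediator)
    med_ids = np.array([f"med_snp{j}" for j in range(n_snps_mediator)])

    per_trait_gamma = {}
    all_ids = [med_ids]
    for spec in trait_specs:
        g = rng.uniform(*gamma_range, spec.n_snps) * rng.choice([-1.0, 1.0], spec.n_snps)
        per_trait_gamma[spec.trait_id] = g
        all_ids.append(np.array([f"{spec.trait_id}_snp{j}" for j in range(spec.n_snps)]))
    ids = np.concatenate(all_ids)
    n_all = len(ids)
    chrom, pos = _layout(n_all, 1)
    eaf = rng.uniform(*eaf_range, n_all)
    ea, oa = _alleles(rng, n_all, palindromic_rate)
    id_index = {v: i for i, v in enumerate(ids)}

    # true associations of every variant with mediator and outcomes
    true_m = np.zeros(n_all)
    true_m[:n_snps_mediator] = delta
    true_out = {o: np.zeros(n_all) for o in outcome_ids}
    for o in outcome_ids:
        true_out[o][:n_snps_mediator] = theta_M[o] * delta
    offset = n_snps_mediator
    for spec in trait_specs:
        g = per_trait_gamma[spec.trait_id]
        sl = slice(offset, offset + spec.n_snps)
        true_m[sl] = spec.beta_to_mediator * g
        for o in outcome_ids:
            th = spec.theta_outcomes.get(o, 0.0)
            true_out[o][sl] = th * g + theta_M[o] * spec.beta_to_mediator * g
        offset += spec.n_snps

    def build(true_beta, n_sample, scramble=True):
        b, s, p = _observe(rng, true_beta, eaf, n_sample)
        df = _frame(ids, chrom, pos, ea, oa, eaf, b, s, p, n_sample)
        if scramble:
            df = _scramble(rng, df, 0.3, 0.1)
        return df

    mediator = SummaryStatSet("t2d", build(true_m, n_mediator_gwas),
                              trait_type="binary-logistic")
    outcomes = {
        o: SummaryStatSet(o, build(true_out[o], n_outcome_gwas),
                          trait_type="binary-logistic")
        for o in outcome_ids
    }

    traits = {}
    offset = n_snps_mediator
    for spec in trait_specs:
        g = per_trait_gamma[spec.trait_id]
        own_ids = ids[offset:offset + spec.n_snps]
        cover = np.concatenate([own_ids, med_ids])
        rows = np.array([id_index[v] for v in cover])
        true_t = np.concatenate([g, spec.reverse_from_mediator * delta])
        b, s, p = _observe(rng, true_t, eaf[rows], n_trait)
        df = _frame(ids[rows], chrom[rows], pos[rows], ea[rows], oa[rows],
                    eaf[rows], b, s, p, n_trait)
        traits[spec.trait_id] = SummaryStatSet(spec.trait_id, df)
        offset += spec.n_snps

    ld = LDMatrix(list(ids), np.eye(n_all))
    truth = {
        "theta_M": theta_M,
        "specs": {s.trait_id: asdict(s) for s in trait_specs},
        "gamma": {k: list(v) for k, v in per_trait_gamma.items()},
        "delta": list(delta),
    }
    return ScreeningStudy(traits, mediator, outcomes, ld, truth)
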