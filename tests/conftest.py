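import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonisedSet, SummaryStatSet


def make_hset(bx, sx, by, so, bm=None, sm=None, ids=None) -> HarmonisedSet:
    """Build a harmonised set directly from effect arrays (test helper)."""
    bx = np.asarray(bx, float)
    k = len(bx)
    cols = {
        "variant_id": ids if ids is not None else [f"v{i}" for i in range(k)],
        "chromosome": ["1"] * k,
        "position": np.arange(k) * 20_000_000 + 1,
        "effect_allele": ["A"] * k,
        "other_allele": ["G"] * k,
        "eaf_exp": np.full(k, 0.3),
        "beta_exp": bx,
        "se_exp": np.asarray(sx, float),
        "pval_exp": np.full(k, 1e-10),
        "n_exp": np.full(k, 100_000),
        "eaf_out": np.full(k, 0.3),
        "beta_out": np.asarray(by, float),
        "se_out": np.asarray(so, float),
        "pval_out": np.full(k, 0.5),
        "n_out": np.full(k, 100_000),
    }
    if bm is not None:
        cols["beta_med"] = np.asarray(bm, float)
        cols["se_med"] = np.asarray(sm, float)
        cols["eaf_med"] = np.full(k, 0.3)
        cols["pval_med"] = np.full(k, 0.5)
        cols["n_med"] = np.full(k, 100_000)
    return HarmonisedSet(pd.DataFrame(cols), exposure_id="x", outcome_id="y",
                         mediator_id="m" if bm is not None else None)


def make_sumstats(trait_id="t", **overrides) -> SummaryStatSet:
    """Small well-formed summary-statistic set (3 variants by default)."""
    base = {
        "variant_id": ["rs1", "rs2", "rs3"],
        "chromosome": ["1", "1", "2"],
        "position": [1000, 30_000_000, 1000],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "eaf": [0.3, 0.2, 0.7],
        "beta": [0.1, -0.2, 0.05],
        "se": [0.01, 0.02, 0.01],
        "pval": [1e-10, 1e-12, 1e-9],
        "n": [10000, 10000, 10000],
    }
    base.update(overrides)
    return SummaryStatSet(trait_id, pd.DataFrame(base))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def engineered_specs():
    """Six-trait study with a constructed stage-2 truth table: two fully
    supportive cause-only traits, three bidirectional traits, and one trait
    whose instrument has only nine variants."""
    from mrmediate import TraitSpec

    th = {"cad": 0.3, "pad": 0.3}
    return [
        TraitSpec("t1_full", 30, beta_to_mediator=0.2, theta_outcomes=dict(th)),
        TraitSpec("t2_full", 30, beta_to_mediator=0.2, theta_outcomes=dict(th)),
        TraitSpec("t3_bidir", 30, beta_to_mediator=0.2,
                  reverse_from_mediator=0.3, theta_outcomes=dict(th)),
        TraitSpec("t4_bidir", 30, beta_to_mediator=0.2,
                  reverse_from_mediator=0.3, theta_outcomes=dict(th)),
        TraitSpec("t5_bidir", 30, beta_to_mediator=0.2,
                  reverse_from_mediator=0.3, theta_outcomes=dict(th)),
        TraitSpec("t6_few", 9, beta_to_mediator=0.2, theta_outcomes=dict(th)),
    ]


EXPECTED_STAGE2 = {
    "t1_full": {"cad": True, "pad": True},
    "t2_full": {"cad": True, "pad": True},
    "t3_bidir": {"cad": False, "pad": False},
    "t4_bidir": {"cad": False, "pad": False},
    "t5_bidir": {"cad": False, "pad": False},
    "t6_few": {"cad": False, "pad": False},
}


def run_engineered_study(seed=0, out_dir=None):
    from mrmediate import (MRConfig, StudyInputs, run_study_inputs,
                           simulate_screening_study)

    study = simulate_screening_study(engineered_specs(), seed=seed)
    inputs = StudyInputs(study.traits, study.mediator, study.outcomes, study.ld)
    cfg = MRConfig(seed=seed, n_boot=50)
    return run_study_inputs(inputs, cfg, out_dir=out_dir, sensitivity=False)


@pytest.fixture(scope="session")
def engineered_result():
    return run_engineered_study(seed=0)


@pytest.fixture(scope="session")
def default_study():
    """One simulated three-sample study at the default conditions."""
    from mrmediate import SimulationConfig, simulate_study

    return simulate_study(SimulationConfig(seed=7))
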