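import numpy as np
import pytest

from regmodules.dataio import ContextLabels, ExpressionMatrix
from regmodules.module_builder import RegulatoryModule
from regmodules.synthdata import SynthConfig, generate, tf_list_for


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 samples, raw scale."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array([[5.0, 1.0, 3.0, 0.0],
                         [1.0, 2.0, 4.0, 8.0],
                         [0.0, 0.0, 7.0, 1.0]]),
    )


@pytest.fixture
def two_modules() -> list[RegulatoryModule]:
    return [
        RegulatoryModule(module_id="A(+)", tf="A", sign="activated",
                         targets=[("x", 0.9), ("y", 0.5)]),
        RegulatoryModule(module_id="B(-)", tf="B", sign="repressed",
                         targets=[("z", 0.7)]),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by scoring/ranking tests (no GRN run)."""
    cfg = SynthConfig(n_contexts=3, samples_per_context=30, n_tfs=6,
                      targets_per_tf=10, n_noise_genes=60, seed=7)
    expr, labels, truth = generate(cfg)
    return cfg, expr, labels, truth


@pytest.fixture(scope="session")
def reference_config() -> SynthConfig:
    """The reference fixture geometry used for end-to-end recovery checks."""
    return SynthConfig(n_contexts=3, samples_per_context=60, planted_per_context=2,
                       beta=1.0, noise_sd=0.3, context_shift=2.0, seed=0)


def true_modules(truth):
    """Gene sets of the generating process as RegulatoryModule objects."""
    mods = []
    for tf, sign, targets in truth.modules:
        mods.append(
            RegulatoryModule(
                module_id=f"{tf}({'+' if sign == 'activated' else '-'})",
                tf=tf, sign=sign,
                targets=[(t, 1.0 - i * 1e-3) for i, t in enumerate(targets)],
            )
        )
    return mods


@pytest.fixture(scope="session")
def small_cohort_modules(small_cohort):
    return true_modules(small_cohort[3])
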