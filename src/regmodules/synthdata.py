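"""Seeded synthetic cohorts with planted regulatory modules.

Emulates the statistical structure the pipeline assumes in real cohorts:
transcription factors driving co-expressed target programs (positively
for activators, negatively for repressors), a background of independent
noise genes, and context-specific TF activity — a subset of TFs is
"planted" per context with a mean shift in that context, making its
module differentially enriched there. Ground truth (which TF drives which
targets with which sign, and which module is specific to which context,
up or down) is returned alongside, so recovery at every pipeline stage is
measurable without external data.

Expression is generated on a latent Gaussian log2 scale and exponentiated
(2^z - 1, clipped at 0), i.e. marginally ~log-normal and non-negative, so
the pipeline's log2(x+1) preprocessing approximately recovers the latent
scale. Each synthetic TF is either a pure activator or a pure repressor
(alternating), so every TF corresponds to exactly one true module and
"planted module" is unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dataio import (
    ContextLabels,
    ExpressionMatrix,
    TFList,
    write_expression,
    write_labels,
    write_tf_list,
)
from .module_builder import ACTIVATED, REPRESSED, module_id_for

_BASE_MEAN = 5.0  # latent log2 mean; keeps 2^z - 1 in a plausible count range


@dataclass
class SynthConfig:
    """Cohort geometry and effect sizes.

    Defaults describe the reference fixture: 3 contexts x 60 samples,
    10 TFs with 20 targets each, 300 noise genes, unit regulation strength,
    target noise sd 0.3, a +2 latent-mean shift for planted TFs in their
    context, and 2 planted TFs per context.
    """

    n_contexts: int = 3
    samples_per_context: int = 60
    n_tfs: int = 10
    targets_per_tf: int = 20
    n_noise_genes: int = 300
    beta: float = 1.0
    noise_sd: float = 0.3
    context_shift: float = 2.0
    planted_per_context: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_contexts", "samples_per_context", "n_tfs",
                     "targets_per_tf", "n_noise_genes", "planted_per_context"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.planted_per_context * self.n_contexts > self.n_tfs:
            raise ValueError("not enough TFs to plant the requested modules")


@dataclass
class GroundTruth:
    """Generating process summary: true modules and their context roles.

    ``modules`` lists (tf, sign, targets); ``context_assignments`` maps a
    planted module_id to (context, direction), where direction is "up" for
    an activator module (its targets rise with the TF shift) and "down"
    for a repressor module.
    """

    modules: list[tuple[str, str, list[str]]]
    context_assignments: dict[str, tuple[str, str]]

    def planted_in(self, context: str) -> list[str]:
        return sorted(
            m for m, (c, _) in self.context_assignments.items() if c == context
        )

    def precision_at_k(self, context: str, ranked_module_ids: list[str], k: int) -> float:
        """Fraction of the top-k ranked modules that are planted in ``context``."""
        planted = set(self.planted_in(context))
        top = ranked_module_ids[:k]
        if not top:
            return 0.0
        return sum(m in planted for m in top) / len(top)

    def to_dict(self) -> dict:
        return {
            "modules": [
                {"tf": tf, "sign": sign, "targets": targets}
                for tf, sign, targets in self.modules
            ],
            "context_assignments": {
                m: {"context": c, "direction": d}
                for m, (c, d) in self.context_assignments.items()
            },
        }


def generate(config: SynthConfig) -> tuple[ExpressionMatrix, ContextLabels, GroundTruth]:
    """Draw one cohort; fully deterministic per config.seed."""
    rng = np.random.default_rng(config.seed)
    contexts = [f"context_{i + 1}" for i in range(config.n_contexts)]
    n_samples = config.n_contexts * config.samples_per_context
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    sample_context = np.repeat(np.arange(config.n_contexts), config.samples_per_context)
    labels = ContextLabels(
        assignments={s: contexts[c] for s, c in zip(sample_ids, sample_context)},
        contexts=contexts,
    )

    tf_names = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    tf_signs = [ACTIVATED if i % 2 == 0 else REPRESSED for i in range(config.n_tfs)]

    # planted TFs: the first planted_per_context * n_contexts TFs, round-robin
    # over contexts so each context gets one activator and one repressor when
    # planted_per_context >= 2
    planted_context: dict[int, int] = {}
    for j in range(config.planted_per_context * config.n_contexts):
        planted_context[j] = j % config.n_contexts

    latent_rows = []
    gene_ids: list[str] = []
    modules: list[tuple[str, str, list[str]]] = []
    context_assignments: dict[str, tuple[str, str]] = {}

    tf_latent = np.empty((config.n_tfs, n_samples))
    for i, (tf, sign) in enumerate(zip(tf_names, tf_signs)):
        mean = np.full(n_samples, _BASE_MEAN)
        if i in planted_context:
            ctx = planted_context[i]
            mean = mean + config.context_shift * (sample_context == ctx)
            direction = "up" if sign == ACTIVATED else "down"
            context_assignments[module_id_for(tf, sign)] = (contexts[ctx], direction)
        tf_latent[i] = rng.normal(mean, 1.0)
        gene_ids.append(tf)
        latent_rows.append(tf_latent[i])

    for i, (tf, sign) in enumerate(zip(tf_names, tf_signs)):
        edge_sign = 1.0 if sign == ACTIVATED else -1.0
        targets = []
        for j in range(config.targets_per_tf):
            name = f"{tf}_T{j + 1:02d}"
            targets.append(name)
            gene_ids.append(name)
            centered = tf_latent[i] - _BASE_MEAN
            latent_rows.append(
                _BASE_MEAN
                + edge_sign * abs(config.beta) * centered
                + rng.normal(0.0, config.noise_sd, n_samples)
            )
        modules.append((tf, sign, targets))

    for j in range(config.n_noise_genes):
        gene_ids.append(f"NOISE{j + 1:04d}")
        latent_rows.append(rng.normal(_BASE_MEAN, 1.0, n_samples))

    latent = np.vstack(latent_rows)
    raw = np.clip(np.exp2(latent) - 1.0, 0.0, None)
    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=raw)
    truth = GroundTruth(modules=modules, context_assignments=context_assignments)
    return expr, labels, truth


def tf_list_for(config: SynthConfig) -> TFList:
    return TFList(symbols={f"TF{i + 1:03d}" for i in range(config.n_tfs)})


def write_fixture(directory: str | Path, config: SynthConfig) -> dict[str, Path]:
    """Write expression/labels/TF-list/ground-truth files in the dialects
    the readers consume; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr, labels, truth = generate(config)
    paths = {
        "expression": directory / "expression.tsv",
        "labels": directory / "labels.tsv",
        "tf_list": directory / "tf_list.txt",
        "ground_truth": directory / "ground_truth.json",
        "config": directory / "synth_config.json",
    }
    write_expression(expr, paths["expression"])
    write_labels(labels, paths["labels"])
    write_tf_list(tf_list_for(config), paths["tf_list"])
    paths["ground_truth"].write_text(json.dumps(truth.to_dict(), indent=2) + "\n")
    paths["config"].write_text(json.dumps(asdict(config), indent=2) + "\n")
    return paths
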