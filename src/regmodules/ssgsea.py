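"""Single-sample gene-set enrichment (ssGSEA) scoring of regulatory modules.

Each sample's genes are rank-normalized (highest expression -> highest
rank score N, lowest -> 1). For a gene set G within a ranked list of N
genes, the raw enrichment score is the sum over list positions of the gap
between two empirical cumulative distribution functions: the in-set ECDF,
weighted by rank score raised to an exponent alpha, and the uniform
out-of-set ECDF:

    ES = sum_{i=1..N} [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{g in G, pos(g) <= i} r_g^alpha / sum_{g in G} r_g^alpha
    P_out(i) = |{g not in G : pos(g) <= i}| / (N - |G|)

Raw scores over all (sample, module) cells are normalized by the global
range of the matrix to give normalized enrichment scores (NES), the
entries of the regulatory-module enrichment score (RMES) matrix: samples
in rows, modules in columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import ExpressionMatrix
from .module_builder import RegulatoryModule

logger = logging.getLogger(__name__)

TIE_BY_SYMBOL = "stable_by_symbol"
NORM_GLOBAL_RANGE = "global_range"
NORM_NONE = "none"


@dataclass
class SsgseaParams:
    """alpha: rank-score exponent (0 = unweighted ECDF gap); default 0.25
    per the convention of the single-sample GSEA method. normalization:
    ``global_range`` divides all raw scores by max-min over the matrix."""

    alpha: float = 0.25
    tie_policy: str = TIE_BY_SYMBOL
    normalization: str = NORM_GLOBAL_RANGE

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.tie_policy != TIE_BY_SYMBOL:
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")
        if self.normalization not in (NORM_GLOBAL_RANGE, NORM_NONE):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class RankedSample:
    """One sample's genes in descending-expression order with rank scores
    N..1 along that order."""

    ordering: list[str]
    rank_scores: np.ndarray

    def __post_init__(self) -> None:
        self.rank_scores = np.asarray(self.rank_scores, dtype=float)
        n = len(self.ordering)
        if self.rank_scores.shape != (n,):
            raise ValueError("rank_scores must align with ordering")
        if np.any(self.rank_scores <= 0):
            raise ValueError("rank scores must be strictly positive")
        self._pos = {g: i for i, g in enumerate(self.ordering)}
        if len(self._pos) != n:
            raise ValueError("ordering contains duplicate genes")

    def position(self, gene: str) -> int:
        return self._pos[gene]

    def __len__(self) -> int:
        return len(self.ordering)


@dataclass
class RMESMatrix:
    """Samples x modules matrix of normalized enrichment scores."""

    sample_ids: list[str]
    module_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids), len(self.module_ids)):
            raise ValueError("RMES score matrix shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("RMES matrix contains non-finite scores")

    def column(self, module_id: str) -> np.ndarray:
        return self.scores[:, self.module_ids.index(module_id)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.sample_ids, columns=self.module_ids)


def rank_normalize(
    sample_expr: np.ndarray, gene_ids: Sequence[str],
    tie_policy: str = TIE_BY_SYMBOL,
) -> RankedSample:
    """Sort one sample's genes by descending expression; assign scores N..1.

    Ties are broken by ascending gene symbol so the ordering (and every
    downstream score) is reproducible. Any strictly monotone transform of
    the expression vector leaves the result unchanged.
    """
    if tie_policy != TIE_BY_SYMBOL:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    sample_expr = np.asarray(sample_expr, dtype=float)
    n = sample_expr.shape[0]
    if n < 2:
        raise ValueError("rank normalization needs at least 2 genes")
    if n != len(gene_ids):
        raise ValueError("expression vector and gene list differ in length")
    order = sorted(range(n), key=lambda i: (-sample_expr[i], gene_ids[i]))
    ordering = [gene_ids[i] for i in order]
    return RankedSample(ordering=ordering, rank_scores=np.arange(n, 0, -1, dtype=float))


def enrichment_score(rs: RankedSample, gene_set: set[str], alpha: float) -> float:
    """Raw ES of ``gene_set`` in one ranked sample (weighted-ECDF gap sum)."""
    n = len(rs)
    if not gene_set:
        raise ValueError("gene set is empty")
    if len(gene_set) >= n:
        raise ValueError("gene set must not cover all ranked genes")
    missing = [g for g in gene_set if g not in rs._pos]
    if missing:
        raise KeyError(f"genes absent from ranked sample: {sorted(missing)[:5]}")
    in_set = np.fromiter((g in gene_set for g in rs.ordering), dtype=bool, count=n)
    weights = np.where(in_set, rs.rank_scores**alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~in_set) / (n - len(gene_set))
    return float(np.sum(p_in - p_out))


def build_rmes(
    expr: ExpressionMatrix,
    modules: Sequence[RegulatoryModule],
    params: SsgseaParams | None = None,
) -> RMESMatrix:
    """Score every module's target-gene set in every sample; normalize.

    The scored set is the module's targets only — the TF labels the module
    but is not a member, because the module is scored as the regulated
    program. With ``global_range`` normalization, NES = ES / (max ES - min
    ES) over the whole matrix; a degenerate matrix (all raw scores equal)
    yields all-zero NES with a warning.
    """
    if params is None:
        params = SsgseaParams()
    if not modules:
        raise ValueError("at least one module is required")
    genes = set(expr.gene_ids)
    gene_sets = []
    for mod in modules:
        missing = set(mod.target_genes) - genes
        if missing:
            raise KeyError(
                f"module {mod.module_id} targets absent from expression matrix: "
                f"{sorted(missing)[:5]}"
            )
        gene_sets.append(set(mod.target_genes))

    n_samples = len(expr.sample_ids)
    raw = np.empty((n_samples, len(modules)))
    for j in range(n_samples):
        rs = rank_normalize(expr.values[:, j], expr.gene_ids, params.tie_policy)
        for k, gset in enumerate(gene_sets):
            raw[j, k] = enrichment_score(rs, gset, params.alpha)

    if params.normalization == NORM_GLOBAL_RANGE:
        spread = raw.max() - raw.min()
        if spread == 0:
            logger.warning(
                "all raw enrichment scores identical; RMES matrix set to zero"
            )
            scores = np.zeros_like(raw)
        else:
            scores = raw / spread
    else:
        scores = raw
    return RMESMatrix(
        sample_ids=list(expr.sample_ids),
        module_ids=[m.module_id for m in modules],
        scores=scores,
    )
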