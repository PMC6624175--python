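"""End-to-end orchestration: expression -> network -> modules -> RMES -> ranking."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import dataio
from .dataio import ContextLabels, ExpressionMatrix, TFList
from .grn_inference import BoostingParams, RegulatoryNetwork, infer_network
from .importance_ranking import DEFAULT_N_TREES, rank_modules
from .module_builder import ModuleBuildParams, RegulatoryModule, build_modules
from .ssgsea import RMESMatrix, SsgseaParams, build_rmes


@dataclass
class PipelineResult:
    expression: ExpressionMatrix  # log-space matrix actually used
    network: RegulatoryNetwork
    modules: list[RegulatoryModule]
    rmes: RMESMatrix
    ranked: dict[str, pd.DataFrame]


def run_pipeline(
    expr_raw: ExpressionMatrix,
    labels: ContextLabels,
    tfs: TFList,
    boosting: BoostingParams | None = None,
    module_params: ModuleBuildParams | None = None,
    ssgsea_params: SsgseaParams | None = None,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    top_n: int | None = None,
    drop_constant_genes: bool = True,
) -> PipelineResult:
    """Run every stage on a raw (non-negative) expression matrix.

    Samples without a context label may be present: they are scored in the
    RMES matrix but excluded from ranking. ``seed`` feeds both the network
    inference (unless a BoostingParams with its own seed is supplied) and
    the ranking forests.
    """
    expr = dataio.preprocess_expression(expr_raw)
    if drop_constant_genes:
        expr = dataio.drop_zero_variance_genes(expr)
    if boosting is None:
        boosting = BoostingParams(seed=seed)
    network = infer_network(expr, tfs, boosting)
    modules = build_modules(network, expr, module_params)
    if not modules:
        raise RuntimeError(
            "no regulatory module survived filtering; relax the thresholds"
        )
    rmes = build_rmes(expr, modules, ssgsea_params)
    ranked = rank_modules(rmes, labels, n_trees=n_trees, seed=seed, top_n=top_n)
    return PipelineResult(
        expression=expr, network=network, modules=modules, rmes=rmes, ranked=ranked
    )
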