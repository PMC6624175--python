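"""Assemble signed regulatory modules from the weighted network.

A regulatory module is a depth-1 tree: one transcription factor at the
root and its surviving target genes as leaves, ranked by regulatory
interaction score. Weak edges are filtered, each TF-target pair is signed
by the Pearson correlation of their expression over all samples, and
edges are partitioned into an activated module TF(+) (positive
correlation throughout) and a repressed module TF(-) (negative
correlation throughout). Motif-based pruning is supported through an
optional user-supplied keep-table hook applied after assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix
from .grn_inference import RegulatoryNetwork

ACTIVATED = "activated"
REPRESSED = "repressed"
DROPPED = "dropped"

_SIGN_SUFFIX = {ACTIVATED: "(+)", REPRESSED: "(-)"}


@dataclass
class ModuleBuildParams:
    """Thresholds governing edge filtering and module assembly.

    min_ris:
        Minimum edge weight to keep (weak-edge filter).
    top_k_per_tf:
        If set, keep at most the k strongest edges per TF.
    rho_min:
        Minimum |Pearson correlation| for an edge to receive a sign.
    min_targets:
        Modules with fewer surviving targets are discarded.
    """

    min_ris: float = 0.001
    top_k_per_tf: int | None = 50
    rho_min: float = 0.03
    min_targets: int = 5

    def __post_init__(self) -> None:
        if self.min_ris < 0:
            raise ValueError("min_ris must be non-negative")
        if self.top_k_per_tf is not None and self.top_k_per_tf < 1:
            raise ValueError("top_k_per_tf must be positive")
        if self.rho_min < 0:
            raise ValueError("rho_min must be non-negative")
        if self.min_targets < 1:
            raise ValueError("min_targets must be positive")


@dataclass
class RegulatoryModule:
    """One TF with a sign and its RIS-ranked targets."""

    module_id: str
    tf: str
    sign: str
    targets: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATED, REPRESSED):
            raise ValueError(f"invalid sign {self.sign!r}")
        if not self.targets:
            raise ValueError(f"module {self.module_id} has no targets")
        names = [t for t, _ in self.targets]
        if len(set(names)) != len(names):
            raise ValueError(f"module {self.module_id} has duplicate targets")
        if self.tf in names:
            raise ValueError(f"module {self.module_id} contains its own TF as target")

    @property
    def target_genes(self) -> list[str]:
        return [t for t, _ in self.targets]

    def __len__(self) -> int:
        return len(self.targets)


def module_id_for(tf: str, sign: str) -> str:
    return f"{tf}{_SIGN_SUFFIX[sign]}"


def filter_edges(net: RegulatoryNetwork, params: ModuleBuildParams) -> RegulatoryNetwork:
    """Keep edges with ris >= min_ris, then optionally the top-k per TF.

    Top-k ties are broken by target symbol so the result is deterministic.
    """
    kept = [(tf, tg, ris) for tf, tg, ris in net.edges if ris >= params.min_ris]
    if params.top_k_per_tf is not None:
        by_tf: dict[str, list[tuple[str, str, float]]] = {}
        for edge in kept:
            by_tf.setdefault(edge[0], []).append(edge)
        kept = []
        for tf in sorted(by_tf):
            edges = sorted(by_tf[tf], key=lambda e: (-e[2], e[1]))
            kept.extend(edges[: params.top_k_per_tf])
    return RegulatoryNetwork(edges=kept)


def sign_edge(
    tf_expr: np.ndarray, target_expr: np.ndarray, rho_min: float
) -> Literal["activated", "repressed", "dropped"]:
    """Classify one edge by the Pearson correlation of TF and target.

    rho >= +rho_min -> activated, rho <= -rho_min -> repressed, otherwise
    (including any constant vector, where the correlation is undefined)
    dropped.
    """
    tf_expr = np.asarray(tf_expr, dtype=float)
    target_expr = np.asarray(target_expr, dtype=float)
    if tf_expr.shape != target_expr.shape:
        raise ValueError("TF and target expression vectors differ in length")
    if tf_expr.size < 3:
        raise ValueError("at least 3 samples are required to sign an edge")
    if np.ptp(tf_expr) == 0 or np.ptp(target_expr) == 0:
        return DROPPED
    rho = stats.pearsonr(tf_expr, target_expr).statistic
    if rho >= rho_min:
        return ACTIVATED
    if rho <= -rho_min:
        return REPRESSED
    return DROPPED


def build_modules(
    net: RegulatoryNetwork,
    expr: ExpressionMatrix,
    params: ModuleBuildParams | None = None,
) -> list[RegulatoryModule]:
    """Filter, sign and partition the network into regulatory modules.

    Correlations are computed on the full (log-space) matrix over all
    samples; module construction is independent of any context labels.
    Modules smaller than ``min_targets`` are discarded, targets are sorted
    by descending RIS (ties by symbol), and the output is sorted by
    module_id.
    """
    if params is None:
        params = ModuleBuildParams()
    genes = set(expr.gene_ids)
    for tf, target, _ in net.edges:
        if tf not in genes:
            raise KeyError(f"TF {tf!r} absent from expression matrix")
        if target not in genes:
            raise KeyError(f"target {target!r} absent from expression matrix")

    filtered = filter_edges(net, params)
    frame = expr.to_frame()
    grouped: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for tf, target, ris in filtered.edges:
        sign = sign_edge(frame.loc[tf].to_numpy(), frame.loc[target].to_numpy(),
                         params.rho_min)
        if sign == DROPPED:
            continue
        grouped.setdefault((tf, sign), []).append((target, ris))

    modules = []
    for (tf, sign), targets in grouped.items():
        if len(targets) < params.min_targets:
            continue
        targets.sort(key=lambda tr: (-tr[1], tr[0]))
        modules.append(
            RegulatoryModule(module_id=module_id_for(tf, sign), tf=tf,
                             sign=sign, targets=targets)
        )
    modules.sort(key=lambda m: m.module_id)
    return modules


def apply_prune_table(
    modules: Iterable[RegulatoryModule], prune_table: pd.DataFrame,
    min_targets: int = 1,
) -> list[RegulatoryModule]:
    """Pruning hook: drop targets flagged keep=False in a (tf, target, keep) table.

    Stands where motif-enrichment pruning would sit in a full deployment;
    any external pruner can express its verdicts in this table. Pairs not
    listed in the table are kept. Modules falling below ``min_targets``
    after pruning are discarded.
    """
    required = {"tf", "target", "keep"}
    if not required.issubset(prune_table.columns):
        raise ValueError(f"prune table needs columns {sorted(required)}")
    drop = {
        (str(r.tf), str(r.target))
        for r in prune_table.itertuples()
        if not bool(r.keep)
    }
    pruned = []
    for mod in modules:
        targets = [(t, r) for t, r in mod.targets if (mod.tf, t) not in drop]
        if len(targets) >= min_targets:
            pruned.append(
                RegulatoryModule(module_id=mod.module_id, tf=mod.tf,
                                 sign=mod.sign, targets=targets)
            )
    return pruned
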