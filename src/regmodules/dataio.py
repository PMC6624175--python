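"""Input parsing, expression preprocessing, and artifact serialization.

The pipeline's raw substrate is a genes x samples expression matrix of
non-negative quantifications (e.g. RSEM expected counts), which is
log2(x+1)-transformed before any inference. Context labels (sample ->
phenotype) and a transcription-factor list complete the inputs. All
intermediate artifacts (networks, modules, enrichment matrices, rankings)
are serialized as plain TSV; module gene sets additionally as GMT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class DataValidationError(ValueError):
    """Raised when an input file or in-memory object violates a contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression matrix.

    Parameters
    ----------
    gene_ids:
        Unique gene symbols, one per row of ``values``.
    sample_ids:
        Unique sample identifiers, one per column of ``values``.
    values:
        2-D float array, shape ``(len(gene_ids), len(sample_ids))``. Raw
        (pre-transform) values must be non-negative; log-space values are
        unconstrained in sign but must be finite.
    is_log_transformed:
        Whether values are in log2(x+1) space.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    is_log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size == 0:
            raise DataValidationError("expression matrix is empty")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("expression matrix contains non-finite values")
        if not self.is_log_transformed and np.any(self.values < 0):
            raise DataValidationError("raw expression values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, is_log_transformed: bool = False) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            is_log_transformed=is_log_transformed,
        )

    def gene_vector(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in expression matrix") from None
        return self.values[i]


@dataclass
class ContextLabels:
    """Mapping from sample identifier to context (phenotype) name.

    ``contexts`` preserves first-appearance order and defines C, the number
    of distinct contexts.
    """

    assignments: dict[str, str]
    contexts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise DataValidationError("context labels are empty")
        seen: list[str] = []
        for ctx in self.assignments.values():
            if ctx not in seen:
                seen.append(ctx)
        if not self.contexts:
            self.contexts = seen
        elif set(self.contexts) != set(seen):
            raise DataValidationError("declared contexts disagree with assignments")

    @property
    def n_contexts(self) -> int:
        return len(self.contexts)

    def samples_in(self, context: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == context]

    def subset(self, sample_ids: Iterable[str]) -> "ContextLabels":
        """Restrict to the given samples, preserving context order."""
        assignments = {s: self.assignments[s] for s in sample_ids if s in self.assignments}
        if not assignments:
            raise DataValidationError("no labeled samples in the requested subset")
        contexts = [c for c in self.contexts if c in set(assignments.values())]
        return ContextLabels(assignments=assignments, contexts=contexts)


@dataclass
class TFList:
    """Set of gene symbols declared to be transcription factors."""

    symbols: set[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise DataValidationError("transcription-factor list is empty")
        self.symbols = set(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a TSV expression matrix into canonical genes x samples form.

    ``orientation`` is ``"genes_in_rows"`` (first column = gene symbols,
    header = sample IDs) or ``"samples_in_rows"`` (transposed dialect, as in
    matrices that list samples in rows and genes in columns).
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if frame.empty:
        raise DataValidationError(f"{path}: empty expression matrix")
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except ValueError:
                raise DataValidationError(
                    f"{path}: non-numeric cell {raw[i, j]!r} at row "
                    f"{frame.index[i]!r}, column {frame.columns[j]!r}"
                ) from None
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise DataValidationError(
            f"{path}: non-finite value at row {frame.index[bad[0]]!r}, "
            f"column {frame.columns[bad[1]]!r}"
        )
    numeric = pd.DataFrame(values, index=[str(i) for i in frame.index],
                           columns=[str(c) for c in frame.columns])
    if orientation == "samples_in_rows":
        numeric = numeric.T
    return ExpressionMatrix.from_frame(numeric)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def preprocess_expression(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(x+1) to every value; refuses to transform twice."""
    if m.is_log_transformed:
        raise DataValidationError("expression matrix is already log-transformed")
    if np.any(m.values < 0):
        raise DataValidationError("negative values cannot be log2(x+1)-transformed")
    return replace(m, values=np.log2(m.values + 1.0), is_log_transformed=True)


def drop_zero_variance_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose expression is identical in every sample.

    Constant genes carry no regulatory signal and only slow inference; by
    default the pipeline removes all-constant rows before fitting.
    """
    keep = np.ptp(m.values, axis=1) > 0
    if not keep.any():
        raise DataValidationError("all genes have zero variance")
    frame = m.to_frame().loc[np.asarray(m.gene_ids)[keep]]
    return ExpressionMatrix.from_frame(frame, is_log_transformed=m.is_log_transformed)


def read_labels(path: str | Path) -> ContextLabels:
    """Read a two-column (sample_id, context) TSV; contexts keep file order."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.empty or frame.shape[1] < 2:
        raise DataValidationError(f"{path}: expected a two-column sample/context table")
    assignments: dict[str, str] = {}
    for sample, ctx in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        sample, ctx = str(sample), str(ctx)
        if sample in assignments:
            raise DataValidationError(f"{path}: duplicate sample identifier {sample!r}")
        assignments[sample] = ctx
    return ContextLabels(assignments=assignments)


def write_labels(labels: ContextLabels, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels.assignments), "context": list(labels.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


def read_tf_list(path: str | Path) -> TFList:
    """Read a transcription-factor list, one gene symbol per line."""
    symbols: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            symbols.append(line)
    _check_unique(symbols, "transcription factor")
    return TFList(symbols=set(symbols))


def write_tf_list(tfs: TFList, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(tfs.symbols)) + "\n")


# ---------------------------------------------------------------------------
# Module serialization (TSV edge list + GMT gene sets)
# ---------------------------------------------------------------------------

MODULE_TSV_COLUMNS = ("module_id", "tf", "sign", "target", "ris")


def write_modules(modules: Sequence, path_tsv: str | Path, path_gmt: str | Path) -> None:
    """Serialize modules as a TSV edge table and a GMT gene-set file.

    TSV rows are one per (module, target) with targets in descending
    regulatory-interaction-score order; the GMT description field encodes
    the TF and sign so that the module set round-trips.
    """
    rows = []
    gmt_lines = []
    for mod in modules:
        for target, ris in mod.targets:
            rows.append((mod.module_id, mod.tf, mod.sign, target, ris))
        genes = "\t".join(t for t, _ in mod.targets)
        gmt_lines.append(f"{mod.module_id}\t{mod.tf}|{mod.sign}\t{genes}")
    pd.DataFrame(rows, columns=MODULE_TSV_COLUMNS).to_csv(path_tsv, sep="\t", index=False)
    Path(path_gmt).write_text("\n".join(gmt_lines) + ("\n" if gmt_lines else ""))


def read_modules(path_tsv: str | Path):
    """Read a module TSV written by :func:`write_modules`."""
    from .module_builder import RegulatoryModule  # local import: avoid cycle

    frame = pd.read_csv(path_tsv, sep="\t", dtype={"module_id": str, "tf": str,
                                                   "sign": str, "target": str})
    modules = []
    if frame.empty:
        return modules
    for module_id, group in frame.groupby("module_id", sort=True):
        targets = list(zip(group["target"], group["ris"].astype(float)))
        targets.sort(key=lambda tr: (-tr[1], tr[0]))
        modules.append(
            RegulatoryModule(
                module_id=str(module_id),
                tf=str(group["tf"].iloc[0]),
                sign=str(group["sign"].iloc[0]),
                targets=targets,
            )
        )
    return modules


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file as {set name: [genes]}; the description is ignored."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise DataValidationError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = parts[2:]
    return sets


# ---------------------------------------------------------------------------
# Network / RMES / ranking serialization
# ---------------------------------------------------------------------------

def write_network(net, path: str | Path) -> None:
    pd.DataFrame(net.edges, columns=["tf", "target", "ris"]).to_csv(
        path, sep="\t", index=False
    )


def read_network(path: str | Path):
    from .grn_inference import RegulatoryNetwork  # local import: avoid cycle

    frame = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    edges = [(str(t), str(g), float(r)) for t, g, r in
             zip(frame["tf"], frame["target"], frame["ris"])]
    return RegulatoryNetwork(edges=edges)


def write_rmes(rmes, path: str | Path) -> None:
    pd.DataFrame(rmes.scores, index=rmes.sample_ids, columns=rmes.module_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_rmes(path: str | Path):
    from .ssgsea import RMESMatrix  # local import: avoid cycle

    frame = pd.read_csv(path, sep="\t", index_col=0)
    return RMESMatrix(
        sample_ids=[str(s) for s in frame.index],
        module_ids=[str(m) for m in frame.columns],
        scores=frame.to_numpy(dtype=float),
    )


def write_ranked_modules(tables: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    """Write per-context ranked module tables as one long TSV."""
    frames = []
    for context, table in tables.items():
        t = table.copy()
        t.insert(0, "context", context)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["context", "rank", "module_id", "fis", "status"]
    )
    out.to_csv(path, sep="\t", index=False)


def write_metrics(report, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
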