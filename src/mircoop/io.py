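"""Readers, writers and validated in-memory containers.

All tables travel as TSV/CSV (delimiter chosen by file extension, ``.csv``
→ comma, anything else → tab), graphs as three-column edge lists, module
sets as GMT-style lines.  Every reader validates the invariants of its
target container and raises :class:`ValidationError` naming the offending
id or cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """An input table violates a container invariant."""


def _delimiter(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for x in ids:
        seen[x] = seen.get(x, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValidationError(f"duplicate {what}: {', '.join(dups)}")


@dataclass
class ExpressionDataset:
    """A labeled samples × miRNAs expression matrix.

    ``labels`` uses the fixed convention case = 1, control = 0.  Both
    classes must be present with at least two samples each, so that
    two-sample t-tests downstream are well defined.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # n samples × m features
    labels: np.ndarray  # n, int {0,1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.feature_ids):
            raise ValidationError(
                f"value matrix is {n}x{m} but there are "
                f"{len(self.sample_ids)} samples and {len(self.feature_ids)} features"
            )
        if self.labels.shape != (n,):
            raise ValidationError("labels length does not match sample count")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"missing/non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValidationError("labels must be 0 (control) or 1 (case)")
        for cls in (0, 1):
            if int(np.sum(self.labels == cls)) < 2:
                raise ValidationError(
                    f"label class {cls} has fewer than 2 samples; "
                    "both groups need >=2 samples"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_samples(self, idx: np.ndarray) -> "ExpressionDataset":
        """New dataset restricted to the given sample positions."""
        idx = np.asarray(idx)
        return ExpressionDataset(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[idx],
            labels=self.labels[idx],
        )

    def feature_index(self, fid: str) -> int:
        try:
            return self.feature_ids.index(fid)
        except ValueError:
            raise KeyError(f"unknown feature id {fid!r}") from None


@dataclass
class KnowledgeTable:
    """Binary miRNA × disease association matrix (rows aligned to features)."""

    feature_ids: list[str]
    disease_ids: list[str]
    assoc: np.ndarray  # m × p, {0,1}

    def __post_init__(self) -> None:
        self.assoc = np.asarray(self.assoc, dtype=float)
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.disease_ids, "disease id")
        if len(self.disease_ids) < 1:
            raise ValidationError("knowledge table needs at least one disease")
        if self.assoc.shape != (len(self.feature_ids), len(self.disease_ids)):
            raise ValidationError("association matrix shape mismatch")
        bad = ~np.isin(self.assoc, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary entry {self.assoc[i, j]!r} at miRNA "
                f"{self.feature_ids[i]!r}, disease {self.disease_ids[j]!r}"
            )


@dataclass
class MappingTable:
    """Probe → miRNA-accession pairs; one probe maps to >=1 accessions."""

    pairs: list[tuple[str, str]]

    def accessions_for(self, probe: str) -> list[str]:
        return sorted({a for p, a in self.pairs if p == probe})

    def as_dict(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p, a in self.pairs:
            out.setdefault(p, [])
            if a not in out[p]:
                out[p].append(a)
        return out


@dataclass
class WeightedGraph:
    """Undirected graph as a symmetric nonnegative weight matrix, zero diagonal."""

    node_ids: list[str]
    weights: np.ndarray  # m × m

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        _check_unique(self.node_ids, "node id")
        m = len(self.node_ids)
        if self.weights.shape != (m, m):
            raise ValidationError("weight matrix shape mismatch")
        if not np.allclose(self.weights, self.weights.T):
            raise ValidationError("weight matrix is not symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValidationError("weight matrix diagonal must be zero")
        if np.any(self.weights < 0):
            raise ValidationError("weights must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def degree(self, node: str) -> float:
        try:
            i = self.node_ids.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None
        return float(self.weights[i].sum())


def read_expression(
    path: str | Path,
    label_col: str | None = None,
    label_file: str | Path | None = None,
    transposed: bool = False,
) -> ExpressionDataset:
    """Read a samples × features table with a header of feature ids.

    Labels come either from a column named ``label_col`` inside the table
    or from a two-column sidecar file (sample_id, label).  With
    ``transposed=True`` the file stores features × samples and is flipped
    on read.
    """
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    if transposed:
        df = df.T
    labels_s: pd.Series
    if label_col is not None:
        if label_col not in df.columns:
            raise ValidationError(f"label column {label_col!r} not found")
        labels_s = df[label_col]
        df = df.drop(columns=[label_col])
    elif label_file is not None:
        lf = pd.read_csv(label_file, sep=_delimiter(label_file), index_col=0, header=None)
        missing = [s for s in df.index if s not in lf.index]
        if missing:
            raise ValidationError(f"labels missing for samples: {', '.join(map(str, missing))}")
        labels_s = lf.loc[df.index, lf.columns[0]]
    else:
        raise ValidationError("one of label_col or label_file is required")
    if df.isna().any().any():
        j = df.columns[df.isna().any()][0]
        i = df.index[df[j].isna()][0]
        raise ValidationError(f"missing value at sample {i!r}, feature {j!r}")
    return ExpressionDataset(
        feature_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
        values=df.to_numpy(dtype=float),
        labels=labels_s.to_numpy(dtype=int),
    )


def write_expression(data: ExpressionDataset, path: str | Path, label_col: str = "label") -> None:
    df = pd.DataFrame(data.values, index=data.sample_ids, columns=data.feature_ids)
    df.insert(0, label_col, data.labels)
    df.to_csv(path, sep=_delimiter(path), index_label="sample_id")


def read_knowledge(path: str | Path, features: Sequence[str]) -> KnowledgeTable:
    """Read a miRNA × disease 0/1 table and align its rows to ``features``.

    Features absent from the file get all-zero rows (counted in a log
    message) rather than being dropped: lack of a database record is not
    evidence against the miRNA, and the expression side still carries
    information for it.
    """
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    if df.shape[1] < 1:
        raise ValidationError("knowledge table has an empty disease set")
    raw = KnowledgeTable(
        feature_ids=[str(i) for i in df.index],
        disease_ids=[str(c) for c in df.columns],
        assoc=df.to_numpy(dtype=float),
    )
    index = {f: i for i, f in enumerate(raw.feature_ids)}
    m, p = len(features), len(raw.disease_ids)
    assoc = np.zeros((m, p))
    missing = []
    for r, f in enumerate(features):
        if f in index:
            assoc[r] = raw.assoc[index[f]]
        else:
            missing.append(f)
    if missing:
        logger.warning(
            "%d of %d features have no knowledge record; assigned all-zero rows",
            len(missing), m,
        )
    return KnowledgeTable(feature_ids=list(features), disease_ids=raw.disease_ids, assoc=assoc)


def write_knowledge(table: KnowledgeTable, path: str | Path) -> None:
    pd.DataFrame(
        table.assoc.astype(int), index=table.feature_ids, columns=table.disease_ids
    ).to_csv(path, sep=_delimiter(path), index_label="feature_id")


def read_mapping(path: str | Path) -> MappingTable:
    """Read a two-column (probe_id, mirna_accession) table, no header required."""
    df = pd.read_csv(path, sep=_delimiter(path), header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError("mapping table needs two columns: probe_id, accession")
    pairs = [(str(p), str(a)) for p, a in zip(df[0], df[1])]
    return MappingTable(pairs=pairs)


def write_graph(graph: WeightedGraph, path: str | Path) -> None:
    """Write an undirected edge list, each edge once with node_a < node_b.

    Weights are serialized with ``repr`` so the read→write round trip is
    exact on the nonzero structure.
    """
    lines = ["node_a\tnode_b\tweight"]
    ids = graph.node_ids
    iu, ju = np.nonzero(np.triu(graph.weights, 1))
    for i, j in zip(iu, ju):
        a, b = sorted((ids[i], ids[j]))
        lines.append(f"{a}\t{b}\t{float(graph.weights[i, j])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_graph(path: str | Path, node_ids: Sequence[str] | None = None) -> WeightedGraph:
    """Inverse of :func:`write_graph`.

    Without ``node_ids`` the node set is the set of endpoints, sorted.
    """
    rows = Path(path).read_text().strip().splitlines()[1:]
    edges = []
    for line in rows:
        a, b, w = line.split("\t")
        edges.append((a, b, float(w)))
    if node_ids is None:
        node_ids = sorted({x for a, b, _ in edges for x in (a, b)})
    index = {f: i for i, f in enumerate(node_ids)}
    w = np.zeros((len(node_ids), len(node_ids)))
    for a, b, x in edges:
        if a not in index or b not in index:
            raise ValidationError(f"edge endpoint {a!r}/{b!r} not in node set")
        w[index[a], index[b]] = w[index[b], index[a]] = x
    return WeightedGraph(node_ids=list(node_ids), weights=w)


def write_modules(modules, path: str | Path) -> None:
    """Write GMT-style lines ``module_id<TAB>auc<TAB>member...``, AUC descending."""
    ranked = sorted(enumerate(modules.modules, 1), key=lambda t: (-t[1][1], t[0]))
    lines = []
    for rank, (_, (members, auc)) in enumerate(ranked, 1):
        lines.append("\t".join([f"M_{rank}", repr(float(auc))] + sorted(members)))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
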