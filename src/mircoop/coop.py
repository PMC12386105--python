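"""Cooperation-network construction.

For every miRNA pair (f_i, f_j) a linear soft-margin SVM is fit on the
two expression columns against the sample groups; its hyperplane
alpha*f_i + beta*f_j + gamma = 0 defines the artificial combinatorial
feature f_com(s) = alpha*f_i(s) + beta*f_j(s) + gamma.  A two-sample
t-test on f_com across the groups decides whether the pair cooperates:
an edge is drawn iff p < p_edge.  Node attributes concatenate the
disease-association vector d(f_i) with the expression profile s(f_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mircoop._svm import fit_linear_svm
from mircoop.config import RunConfig
from mircoop.io import ExpressionDataset, KnowledgeTable, WeightedGraph

logger = logging.getLogger(__name__)


@dataclass
class PairHyperplane:
    """Linear decision boundary alpha*f_i + beta*f_j + gamma = 0.

    ``mean``/``scale`` record the per-feature standardization applied
    before fitting so that evaluation reuses exactly the same transform.
    """

    i: int
    j: int
    alpha: float
    beta: float
    gamma: float
    mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    scale: np.ndarray = field(default_factory=lambda: np.ones(2))

    def __post_init__(self) -> None:
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("degenerate hyperplane: alpha = beta = 0")


@dataclass
class CooperationNetwork:
    graph: WeightedGraph              # binary adjacency A_co
    attributes: np.ndarray            # X_co, m × (p + n)
    pair_pvalues: dict[tuple[int, int], float]


def fit_pair_hyperplane(
    data: ExpressionDataset, i: int, j: int, C: float = 1.0, standardize: bool = True
) -> PairHyperplane | None:
    """Fit the pairwise linear SVM; ``None`` if a column is constant.

    A zero-variance column after standardization carries no pairwise
    signal, so the pair is skipped (no edge) rather than fit.
    """
    X = data.values[:, [i, j]]
    mean = X.mean(axis=0) if standardize else np.zeros(2)
    std = X.std(axis=0, ddof=0)
    if standardize and np.any(std == 0):
        logger.info("pair (%d, %d) skipped: zero-variance feature", i, j)
        return None
    scale = std if standardize else np.ones(2)
    Xs = (X - mean) / scale
    w, b = fit_linear_svm(Xs, data.labels, C)
    return PairHyperplane(i=i, j=j, alpha=float(w[0]), beta=float(w[1]), gamma=b,
                          mean=mean, scale=scale)


def combinatorial_feature(h: PairHyperplane, data: ExpressionDataset) -> np.ndarray:
    """Per-sample value of f_com under the hyperplane's own standardization."""
    X = (data.values[:, [h.i, h.j]] - h.mean) / h.scale
    return h.alpha * X[:, 0] + h.beta * X[:, 1] + h.gamma


def edge_significance(values: np.ndarray, labels: np.ndarray, variant: str = "welch") -> float:
    """Two-sided two-sample t-test p-value of a per-sample score.

    Degenerate case: zero variance in both groups returns p = 1 when the
    means agree (no evidence) and p = 0 when they differ (perfect,
    noiseless separation).
    """
    a = np.asarray(values)[np.asarray(labels) == 1]
    b = np.asarray(values)[np.asarray(labels) == 0]
    if a.size < 2 or b.size < 2:
        raise ValueError("each class needs >=2 samples for a t-test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        logger.info("degenerate t-test (zero variance both groups): p=%g", p)
        return p
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.pvalue)


def node_attributes(
    data: ExpressionDataset, knowledge: KnowledgeTable | None
) -> np.ndarray:
    """X_co rows: [d(f_i) | s(f_i)]; knowledge block omitted when ``None``."""
    expr = data.values.T  # m × n
    if knowledge is None:
        return expr.copy()
    if knowledge.feature_ids != data.feature_ids:
        raise ValueError("knowledge table is not aligned to the dataset features")
    return np.hstack([knowledge.assoc, expr])


def build_cooperation_network(
    data: ExpressionDataset,
    knowledge: KnowledgeTable | None,
    config: RunConfig,
) -> CooperationNetwork:
    """Enumerate all m(m-1)/2 pairs and assemble A_co plus attributes.

    The full quadratic enumeration is retained deliberately: at the
    feature counts this method targets (a few hundred miRNAs) it runs in
    minutes on one CPU and avoids any screening bias.  An optional
    variance prefilter (``config.variance_prefilter``) can skip
    near-constant pairs.
    """
    m = data.n_features
    if m < 2:
        raise ValueError("need at least 2 features to build a cooperation network")
    n = data.n_samples
    variances = data.values.var(axis=0, ddof=0)

    pairs: list[tuple[int, int]] = []
    fcoms: list[np.ndarray] = []
    for i in range(m):
        for j in range(i + 1, m):
            if config.variance_prefilter > 0 and (
                variances[i] < config.variance_prefilter
                or variances[j] < config.variance_prefilter
            ):
                continue
            h = fit_pair_hyperplane(data, i, j, C=config.svm_C, standardize=config.standardize)
            if h is None:
                continue
            pairs.append((i, j))
            fcoms.append(combinatorial_feature(h, data))

    A = np.zeros((m, m))
    pvals: dict[tuple[int, int], float] = {}
    if pairs:
        V = np.column_stack(fcoms)  # n × n_pairs
        a = V[data.labels == 1]
        b = V[data.labels == 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, equal_var=(config.t_test_variant == "student"), axis=0)
        pv = np.asarray(res.pvalue, dtype=float)
        # vectorized call leaves NaN where both groups are constant
        for col, (i, j) in enumerate(pairs):
            p = pv[col]
            if np.isnan(p):
                p = edge_significance(V[:, col], data.labels, config.t_test_variant)
            pvals[(i, j)] = float(p)
            if p < config.p_edge:
                A[i, j] = A[j, i] = 1.0

    graph = WeightedGraph(node_ids=list(data.feature_ids), weights=A)
    X = node_attributes(data, knowledge if config.use_knowledge else None)
    return CooperationNetwork(graph=graph, attributes=X, pair_pvalues=pvals)
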