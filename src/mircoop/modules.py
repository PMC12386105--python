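"""Greedy AUC-guided module search and the per-module SVM voting ensemble.

Module growth starts from the node with the largest weighted degree,
repeatedly pulls in the neighbour across the heaviest outgoing edge, and
keeps it if the module's cross-validated AUC improves — otherwise keeps
it with probability Prob_t = 1 - exp((AUC_cmn - 1)/cmn), a simulated-
annealing-style escape from local optima.  Found modules are removed
from the graph and the search repeats until the edge set is empty or
``max_modules`` is reached.  The top-k modules by AUC each train a
standardized linear SVM; sample labels come from majority voting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from mircoop._svm import fit_linear_svm
from mircoop.config import RunConfig
from mircoop.io import ExpressionDataset, WeightedGraph

logger = logging.getLogger(__name__)


@dataclass
class ModuleSet:
    """Disjoint feature subsets with AUC scores, ordered as found."""

    modules: list[tuple[frozenset, float]]
    source_graph_id: str = ""

    def __post_init__(self) -> None:
        seen: set = set()
        for members, auc in self.modules:
            if seen & members:
                raise ValueError("modules are not pairwise disjoint")
            seen |= members
            if not 0.0 <= auc <= 1.0:
                raise ValueError("module AUC outside [0, 1]")

    def __len__(self) -> int:
        return len(self.modules)


@dataclass
class LinearSVMModel:
    """Standardized linear SVM: z-score columns, then a soft-margin fit.

    Kept deliberately lean (no estimator framework) because module search
    fits tens of thousands of these on tiny column subsets.
    """

    mean: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, C: float, standardize: bool = True
            ) -> "LinearSVMModel":
        if standardize:
            mean = X.mean(axis=0)
            scale = X.std(axis=0, ddof=0)
            scale = np.where(scale == 0, 1.0, scale)
        else:
            mean = np.zeros(X.shape[1])
            scale = np.ones(X.shape[1])
        w, b = fit_linear_svm((X - mean) / scale, y, C)
        return cls(mean=mean, scale=scale, coef=w, intercept=b)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.mean) / self.scale) @ self.coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


@dataclass
class VotingEnsemble:
    """One fitted linear SVM per module; prediction by majority vote."""

    classifiers: list[LinearSVMModel]
    module_features: list[list[str]]
    module_aucs: list[float]

    @property
    def k(self) -> int:
        return len(self.classifiers)


def node_importance(graph: WeightedGraph, node: str) -> float:
    """Weighted degree: the sum of weights of edges adjacent to the node."""
    return graph.degree(node)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formula, ties counted as 0.5."""
    labels = np.asarray(labels)
    ranks = rankdata(scores)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def module_auc(data: ExpressionDataset, members, config: RunConfig) -> float:
    """AUC of a candidate module on the training samples.

    Default mode is seeded stratified 5-fold cross-validation: a linear
    SVM is fit on the member columns per fold and the held-out decision
    scores are pooled into one rank-based AUC, which guards against the
    trivially overfit resubstitution AUC of larger modules.  Folds are
    reduced when a class is too small to stratify.
    """
    members = sorted(members)
    if not members:
        raise ValueError("empty module")
    cols = [data.feature_index(f) for f in members]
    X = data.values[:, cols]
    y = data.labels

    if config.auc_mode == "resubstitution":
        clf = LinearSVMModel.fit(X, y, config.svm_C, config.standardize)
        return rank_auc(clf.decision_function(X), y)

    min_class = int(min(np.sum(y == 0), np.sum(y == 1)))
    folds = min(config.auc_folds, min_class)
    if folds < config.auc_folds:
        logger.info("reduced AUC folds to %d (smallest class)", folds)
    if folds < 2:
        clf = LinearSVMModel.fit(X, y, config.svm_C, config.standardize)
        return rank_auc(clf.decision_function(X), y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed % (2**32))
    scores = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        clf = LinearSVMModel.fit(X[train_idx], y[train_idx], config.svm_C, config.standardize)
        scores[test_idx] = clf.decision_function(X[test_idx])
    return rank_auc(scores, y)


def acceptance_probability(auc_cmn: float, cmn: int) -> float:
    """Prob_t = 1 - exp((AUC_cmn - 1)/cmn); 0 iff AUC_cmn = 1, decreasing in AUC."""
    if cmn < 1:
        raise ValueError("cmn must be a positive integer")
    return float(1.0 - np.exp((auc_cmn - 1.0) / cmn))


def grow_module(
    graph: WeightedGraph,
    data: ExpressionDataset,
    seed_node: str,
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[frozenset, float]:
    """Seed-and-extend one module from ``seed_node``.

    Candidate = outside endpoint of the heaviest module-to-outside edge
    (weight ties broken by best AUC-when-added, then smallest id).  A
    strict AUC improvement is accepted; otherwise acceptance is drawn
    from Prob_t.  The first rejection, or running out of outgoing edges,
    terminates extension.
    """
    ids = graph.node_ids
    index = {f: i for i, f in enumerate(ids)}
    if seed_node not in index:
        raise KeyError(f"unknown node {seed_node!r}")
    W = graph.weights
    members = [seed_node]
    in_module = np.zeros(len(ids), dtype=bool)
    in_module[index[seed_node]] = True
    current_auc = module_auc(data, members, config)

    while True:
        sub = W[in_module][:, ~in_module]
        if sub.size == 0 or sub.max() <= 0:
            break
        best_w = sub.max()
        outside = np.flatnonzero(~in_module)
        cand_cols = np.unique(np.nonzero(np.isclose(sub, best_w) & (sub > 0))[1])
        candidates = [ids[outside[c]] for c in cand_cols]
        if len(candidates) == 1:
            cand = candidates[0]
            cand_auc = module_auc(data, members + [cand], config)
        else:
            scored = [(module_auc(data, members + [c], config), c) for c in sorted(candidates)]
            cand_auc, cand = min(scored, key=lambda t: (-t[0], t[1]))
        cmn = len(members) + 1
        if cand_auc > current_auc:
            accept = True
        else:
            accept = rng.random() < acceptance_probability(cand_auc, cmn)
        if not accept:
            break
        members.append(cand)
        in_module[index[cand]] = True
        current_auc = cand_auc

    return frozenset(members), current_auc


def find_modules(
    graph: WeightedGraph,
    data: ExpressionDataset,
    config: RunConfig,
    rng: np.random.Generator,
) -> ModuleSet:
    """Repeated seed-and-extend with node removal.

    Seeds are the maximum-importance non-isolated nodes (ties to the
    smallest id); found module nodes and their incident edges are
    deleted before the next round.
    """
    ids = list(graph.node_ids)
    W = graph.weights.copy()
    found: list[tuple[frozenset, float]] = []

    while len(found) < config.max_modules:
        degrees = W.sum(axis=1)
        alive = degrees > 0
        if not alive.any():
            break
        best = min(
            (i for i in range(len(ids)) if alive[i]),
            key=lambda i: (-degrees[i], ids[i]),
        )
        working = WeightedGraph(node_ids=ids, weights=W)
        members, auc = grow_module(working, data, ids[best], config, rng)
        found.append((members, auc))
        for f in members:
            idx = ids.index(f)
            W[idx, :] = 0.0
            W[:, idx] = 0.0

    return ModuleSet(modules=found, source_graph_id="G_Net")


def select_top_k(modules: ModuleSet, k: int) -> ModuleSet:
    """Keep the k highest-AUC modules (ties: smaller size, then first id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(modules) == 0:
        raise ValueError("no modules found; cannot select biomarkers")
    ranked = sorted(
        modules.modules, key=lambda t: (-t[1], len(t[0]), min(t[0]))
    )
    if len(ranked) < k:
        logger.warning("only %d modules available for k=%d", len(ranked), k)
    return ModuleSet(modules=ranked[: min(k, len(ranked))], source_graph_id=modules.source_graph_id)


def fit_ensemble(data: ExpressionDataset, modules: ModuleSet, config: RunConfig) -> VotingEnsemble:
    if len(modules) == 0:
        raise ValueError("cannot fit an ensemble on an empty module set")
    classifiers, feats, aucs = [], [], []
    for members, auc in modules.modules:
        cols = sorted(members)
        X = data.values[:, [data.feature_index(f) for f in cols]]
        clf = LinearSVMModel.fit(X, data.labels, config.svm_C, config.standardize)
        classifiers.append(clf)
        feats.append(cols)
        aucs.append(auc)
    return VotingEnsemble(classifiers=classifiers, module_features=feats, module_aucs=aucs)


def predict(ensemble: VotingEnsemble, samples: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels and the per-sample vote tally for class 1.

    An exact tie (even k) resolves by the sign of the mean decision
    score across base classifiers.
    """
    n = samples.n_samples
    votes = np.zeros((n, ensemble.k), dtype=int)
    scores = np.zeros((n, ensemble.k))
    for c, (clf, feats) in enumerate(zip(ensemble.classifiers, ensemble.module_features)):
        for f in feats:
            if f not in samples.feature_ids:
                raise KeyError(f"sample set is missing feature {f!r}")
        X = samples.values[:, [samples.feature_index(f) for f in feats]]
        votes[:, c] = clf.predict(X)
        scores[:, c] = clf.decision_function(X)
    tally = votes.sum(axis=1)
    labels = np.where(tally * 2 > ensemble.k, 1, 0)
    ties = tally * 2 == ensemble.k
    if ties.any():
        logger.info("%d tied votes resolved by mean decision score", int(ties.sum()))
        labels[ties] = (scores[ties].mean(axis=1) > 0).astype(int)
    return labels, tally
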