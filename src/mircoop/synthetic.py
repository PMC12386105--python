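"""Synthetic two-group expression + knowledge benchmark with planted modules.

The generator emulates the data regime the method targets: a few dozen
samples per group, a few hundred miRNAs, of which small planted modules
are (a) equicorrelated within the module and (b) mean-shifted in cases,
while background features are independent noise in both groups.  The
knowledge matrix realizes the assumption that functionally similar
miRNAs share disease associations: every planted module gets a distinct
disease block whose rows its members share, background rows are sparse
random, and every entry is then flipped independently with probability
``knowledge_flip`` to model database noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mircoop.io import ExpressionDataset, KnowledgeTable


@dataclass
class ModuleSpec:
    size: int
    rho: float = 0.6     # within-module equicorrelation
    delta: float = 1.5   # case-group mean shift (in units of the unit feature SD)

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic benchmark instance."""

    n_per_group: int = 30
    m: int = 120
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [ModuleSpec(8), ModuleSpec(8), ModuleSpec(8)]
    )
    p: int = 20                  # diseases
    knowledge_flip: float = 0.05
    noise_sd: float = 1.0
    background_assoc_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(ms.size for ms in self.modules) > self.m:
            raise ValueError("planted modules do not fit into m features")
        if not 0 <= self.knowledge_flip < 0.5:
            raise ValueError("knowledge_flip must be in [0, 0.5)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_per_group < 2:
            raise ValueError("need >=2 samples per group")


@dataclass
class GroundTruth:
    module_of: np.ndarray        # m, planted module index or -1 for background
    differential: np.ndarray     # m, bool: feature carries a group mean shift
    true_assoc: np.ndarray       # m × p association matrix before flips

    def planted_modules(self, feature_ids: list[str]) -> list[set]:
        out = []
        for t in range(int(self.module_of.max()) + 1 if self.module_of.size else 0):
            out.append({feature_ids[i] for i in np.flatnonzero(self.module_of == t)})
        return out


def simulate(spec: SimulationSpec) -> tuple[ExpressionDataset, KnowledgeTable, GroundTruth]:
    """Draw one dataset; fully determined by ``spec.seed``.

    Module features are unit-variance equicorrelated Gaussians (one
    shared factor per module), shifted by +delta in cases only.
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_group
    labels = np.array([1] * spec.n_per_group + [0] * spec.n_per_group)

    # scatter module members over the feature axis so nothing depends on order
    perm = rng.permutation(spec.m)
    module_of = np.full(spec.m, -1)
    pos = 0
    for t, ms in enumerate(spec.modules):
        module_of[perm[pos : pos + ms.size]] = t
        pos += ms.size

    values = rng.normal(0.0, spec.noise_sd, size=(n, spec.m))
    differential = np.zeros(spec.m, dtype=bool)
    for t, ms in enumerate(spec.modules):
        cols = np.flatnonzero(module_of == t)
        g = rng.normal(size=(n, 1))                       # shared module factor
        e = rng.normal(size=(n, ms.size))
        block = np.sqrt(ms.rho) * g + np.sqrt(1.0 - ms.rho) * e
        block[labels == 1] += ms.delta
        values[:, cols] = block
        differential[cols] = ms.delta > 0

    # knowledge: one distinct disease block per module
    n_mod = len(spec.modules)
    block_size = max(1, spec.p // max(1, 2 * n_mod)) if n_mod else 0
    true_assoc = (rng.random((spec.m, spec.p)) < spec.background_assoc_rate).astype(float)
    for t in range(n_mod):
        cols = np.flatnonzero(module_of == t)
        lo = (t * block_size) % max(spec.p, 1)
        dis = [(lo + b) % spec.p for b in range(block_size)]
        true_assoc[np.ix_(cols, range(spec.p))] = 0.0
        for d in dis:
            true_assoc[cols, d] = 1.0
    flips = rng.random((spec.m, spec.p)) < spec.knowledge_flip
    assoc = np.abs(true_assoc - flips.astype(float))

    width = len(str(spec.m))
    feature_ids = [f"mir-{i:0{width}d}" for i in range(spec.m)]
    sample_ids = [f"case_{i:03d}" for i in range(spec.n_per_group)] + [
        f"ctrl_{i:03d}" for i in range(spec.n_per_group)
    ]
    disease_ids = [f"D{j:02d}" for j in range(spec.p)]

    data = ExpressionDataset(
        feature_ids=feature_ids, sample_ids=sample_ids, values=values, labels=labels
    )
    knowledge = KnowledgeTable(feature_ids=feature_ids, disease_ids=disease_ids, assoc=assoc)
    truth = GroundTruth(module_of=module_of, differential=differential, true_assoc=true_assoc)
    return data, knowledge, truth


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def score_recovery(found, truth: GroundTruth, feature_ids: list[str]) -> tuple[list[float], float]:
    """Best Jaccard of each planted module against the found modules; mean."""
    planted = truth.planted_modules(feature_ids)
    found_sets = [set(members) for members, _ in found.modules] or [set()]
    best = [max(jaccard(pl, fs) for fs in found_sets) for pl in planted]
    mean = float(np.mean(best)) if best else 0.0
    return best, mean


def cross_module_false_edge_fraction(graph, truth: GroundTruth, feature_ids: list[str]) -> float:
    """Fraction of edges joining two different planted modules or a module
    and the background — edges the generative model did not plant."""
    index = {f: i for i, f in enumerate(feature_ids)}
    W = graph.weights
    iu, ju = np.nonzero(np.triu(W, 1))
    if len(iu) == 0:
        return 0.0
    mo = truth.module_of
    false = 0
    for i, j in zip(iu, ju):
        a, b = mo[index[graph.node_ids[i]]], mo[index[graph.node_ids[j]]]
        if a == -1 or b == -1 or a != b:
            false += 1
    return false / len(iu)
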