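"""Graph auto-encoder enhancement of the cooperation network.

A two-layer graph-convolutional encoder maps the cooperation network and
its node attributes to latent representations

    Z = A_hat @ ELU(A_hat @ X @ W0) @ W1,    A_hat = D^{-1/2} (A + I) D^{-1/2},

and an inner-product decoder sigmoid(Z Z^T) reconstructs the adjacency.
Training minimizes

    L_total = L_rec + lambda1 * L_fc + lambda2 * L_mp

where L_rec is the (optionally negative-sampled) MSE between adjacency
and reconstruction, L_fc ties the Gaussian interaction-profile (GIP)
kernel of the latent rows to the GIP kernel of the disease-association
rows (functional consistency), and L_mp is a supervised-contrastive
"difference prompt" on a linear discriminator head, with pseudo-labels
from per-feature differential-expression t-tests.

Everything is plain numpy with analytic gradients (derived by hand and
verified against finite differences in the test suite) and an Adam
update loop, so training is deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from mircoop.config import RunConfig
from mircoop.coop import CooperationNetwork, edge_significance
from mircoop.io import ExpressionDataset, KnowledgeTable, WeightedGraph

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# building blocks


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2} (A + I) D^{-1/2}.

    Self-loops guarantee strictly positive degrees, so the inverse root
    always exists.
    """
    A = np.asarray(A, dtype=float)
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GAEParameters:
    """Trainable weights: encoder W0, W1 and linear discriminator head D_L."""

    W0: np.ndarray   # (p+n) × h1
    W1: np.ndarray   # h1 × h2
    D_L: np.ndarray  # h2 × h_d
    init_seed: int = 0

    def copy(self) -> "GAEParameters":
        return GAEParameters(self.W0.copy(), self.W1.copy(), self.D_L.copy(), self.init_seed)


@dataclass
class LatentRepresentation:
    Z: np.ndarray          # m × h2
    node_ids: list[str]


@dataclass
class TrainingTrace:
    """Per-epoch loss components; lengths equal the epoch count."""

    L_rec: np.ndarray
    L_fc: np.ndarray
    L_mp: np.ndarray
    L_total: np.ndarray
    seed: int


def init_parameters(
    in_dim: int, hidden_dims: tuple[int, int], disc_dim: int, seed: int
) -> GAEParameters:
    """Seeded Glorot-style scaled-uniform initialization."""
    rng = np.random.default_rng(seed)
    h1, h2 = hidden_dims

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return GAEParameters(
        W0=glorot(in_dim, h1), W1=glorot(h1, h2), D_L=glorot(h2, disc_dim), init_seed=seed
    )


def encode(A_hat: np.ndarray, X: np.ndarray, params: GAEParameters) -> np.ndarray:
    """Z = A_hat @ ELU(A_hat @ X @ W0) @ W1."""
    if X.shape[1] != params.W0.shape[0]:
        raise ValueError(
            f"attribute width {X.shape[1]} does not match W0 rows {params.W0.shape[0]}"
        )
    H = elu(A_hat @ X @ params.W0)
    return A_hat @ H @ params.W1


def decode(Z: np.ndarray) -> np.ndarray:
    """Inner-product decoder sigmoid(Z Z^T); symmetric, entries in (0,1)."""
    return sigmoid(Z @ Z.T)


def reconstruction_loss(
    A: np.ndarray, A_rec: np.ndarray, entries: tuple[np.ndarray, np.ndarray] | None = None
) -> float:
    """MSE between adjacency and reconstruction.

    ``entries`` restricts the mean to an explicit (rows, cols) entry set
    (the negative-sampling path); ``None`` means the full matrix.
    """
    if A.shape != A_rec.shape:
        raise ValueError("shape mismatch between adjacency and reconstruction")
    if entries is None:
        return float(np.mean((A - A_rec) ** 2))
    r, c = entries
    return float(np.mean((A[r, c] - A_rec[r, c]) ** 2))


def gip_similarity(vectors: np.ndarray, bandwidth_scale: float = 1.0) -> np.ndarray:
    """Gaussian interaction-profile kernel on the rows of ``vectors``.

    The bandwidth is r = bandwidth_scale / mean_k ||row_k||^2, so the
    kernel adapts to the overall profile scale.  All-zero input is an
    error: the bandwidth is undefined without at least one nonzero row.
    """
    M = np.asarray(vectors, dtype=float)
    q = np.sum(M * M, axis=1)
    mu = float(q.mean())
    if mu == 0.0:
        raise ValueError("all profile rows are zero; GIP bandwidth undefined")
    r = bandwidth_scale / mu
    D = np.maximum(q[:, None] + q[None, :] - 2.0 * (M @ M.T), 0.0)
    return np.exp(-r * D)


def functional_consistency_loss(GS: np.ndarray, GS_prime: np.ndarray) -> float:
    """Squared Frobenius distance ||GS - GS'||_F^2."""
    if GS.shape != GS_prime.shape:
        raise ValueError("similarity matrices differ in shape")
    return float(np.sum((GS - GS_prime) ** 2))


def knowledge_similarity(assoc: np.ndarray) -> np.ndarray:
    """GIP similarity target used by the consistency constraint.

    The raw kernel assigns similarity 1 to two miRNAs that both lack any
    disease record (two all-zero profiles are "identical"), which is an
    artifact of missing knowledge, not functional evidence.  Such
    empty-empty pairs get target similarity 0 instead; the diagonal
    stays 1.
    """
    GS = gip_similarity(assoc)
    empty = np.asarray(assoc).sum(axis=1) == 0
    both_empty = empty[:, None] & empty[None, :]
    np.fill_diagonal(both_empty, False)
    GS[both_empty] = 0.0
    return GS


def assign_pseudo_labels(data: ExpressionDataset, variant: str = "welch") -> np.ndarray:
    """Boolean per-feature pseudo-label: True (y0) iff the per-feature
    two-sample t-test on raw expression has p < 0.05."""
    m = data.n_features
    labels = np.zeros(m, dtype=bool)
    for i in range(m):
        p = edge_significance(data.values[:, i], data.labels, variant)
        labels[i] = p < 0.05
    return labels


def difference_prompt_loss(
    Z: np.ndarray,
    pseudo_labels: np.ndarray,
    D_L: np.ndarray,
    tau: float,
    normalize: bool = True,
) -> float:
    """Supervised-contrastive loss over discriminator outputs u_i = D_L^T Z_i.

    For each node, same-pseudo-label peers are positives and all other
    nodes are contrast candidates; a node whose pseudo-label class is a
    singleton has no positives and its term is skipped.
    """
    loss, _, _ = _difference_prompt_loss_grads(Z, pseudo_labels, D_L, tau, normalize)
    return loss


def _difference_prompt_loss_grads(Z, pseudo_labels, D_L, tau, normalize):
    m = Z.shape[0]
    if m < 2:
        raise ValueError("difference prompt needs at least 2 nodes")
    V = Z @ D_L
    if normalize:
        norms = np.maximum(np.linalg.norm(V, axis=1, keepdims=True), 1e-12)
        U = V / norms
    else:
        U = V
    logits = (U @ U.T) / tau
    np.fill_diagonal(logits, -np.inf)
    mx = logits.max(axis=1, keepdims=True)
    lse = mx[:, 0] + np.log(np.sum(np.exp(logits - mx), axis=1))

    y = np.asarray(pseudo_labels)
    same = (y[:, None] == y[None, :])
    np.fill_diagonal(same, False)
    cnt = same.sum(axis=1)
    active = cnt > 0
    if not active.all():
        logger.info("%d singleton-pseudo-label nodes skipped in L_mp", int((~active).sum()))

    # loss_i = -(1/|B_i|) sum_{b in B_i} (logit_ib - lse_i)
    with np.errstate(invalid="ignore"):
        pos_sum = np.where(same, logits, 0.0).sum(axis=1)
    loss_terms = -(pos_sum / np.maximum(cnt, 1)) + lse
    loss = float(loss_terms[active].sum())

    # gradient wrt logits: softmax minus target distribution, active rows only
    P = np.exp(logits - lse[:, None])
    np.fill_diagonal(P, 0.0)
    T = same / np.maximum(cnt, 1)[:, None]
    G = np.where(active[:, None], P - T, 0.0)

    dU = (G @ U + G.T @ U) / tau
    if normalize:
        dV = (dU - np.sum(U * dU, axis=1, keepdims=True) * U) / norms
    else:
        dV = dU
    dD_L = Z.T @ dV
    dZ = dV @ D_L.T
    return loss, dZ, dD_L


def total_loss(
    components: tuple[float, float, float],
    lambda1: float,
    lambda2: float,
    use_knowledge: bool = True,
    use_difference_prompt: bool = True,
) -> float:
    """L_total = L_rec + lambda1*L_fc + lambda2*L_mp, dropped terms contribute 0."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("balance factors must be nonnegative")
    L_rec, L_fc, L_mp = components
    total = L_rec
    if use_knowledge:
        total += lambda1 * L_fc
    if use_difference_prompt:
        total += lambda2 * L_mp
    return float(total)


# ---------------------------------------------------------------------------
# training


def _objective_and_grads(
    params: GAEParameters,
    A_hat: np.ndarray,
    X: np.ndarray,
    A: np.ndarray,
    GS: np.ndarray | None,
    pseudo_labels: np.ndarray | None,
    config: RunConfig,
    entries: tuple[np.ndarray, np.ndarray] | None = None,
    fc_mask: np.ndarray | None = None,
):
    """Forward pass and analytic gradients of L_total wrt (W0, W1, D_L).

    Returns (losses dict, grads dict).  ``entries`` is the reconstruction
    entry set for negative sampling; None = full-matrix MSE.  ``fc_mask``
    restricts the functional-consistency loss to an entry subset —
    training masks out pairs involving a miRNA with an empty disease
    profile, whose GIP similarity of 1 is an artifact of the kernel
    (two all-zero profiles are "identical"), not functional evidence.
    """
    AX = A_hat @ X
    H0 = AX @ params.W0
    H = elu(H0)
    AH = A_hat @ H
    Z = AH @ params.W1
    m = Z.shape[0]

    # --- reconstruction
    S = Z @ Z.T
    A_rec = sigmoid(S)
    if entries is None:
        diff = A_rec - A
        L_rec = float(np.mean(diff**2))
        M = (2.0 / (m * m)) * diff * A_rec * (1.0 - A_rec)
    else:
        r_idx, c_idx = entries
        k = len(r_idx)
        diff = A_rec[r_idx, c_idx] - A[r_idx, c_idx]
        L_rec = float(np.mean(diff**2))
        M = np.zeros_like(A_rec)
        M[r_idx, c_idx] = (2.0 / k) * diff * A_rec[r_idx, c_idx] * (1.0 - A_rec[r_idx, c_idx])
    dZ = M @ Z + M.T @ Z

    # --- functional consistency
    L_fc = 0.0
    if config.use_knowledge and GS is not None:
        q = np.sum(Z * Z, axis=1)
        mu = float(q.mean())
        if mu == 0.0:
            GS_prime = np.ones_like(GS)  # all latent rows identical at zero
            diff_fc = GS_prime - GS
            if fc_mask is not None:
                diff_fc = diff_fc * fc_mask
            L_fc = float(np.sum(diff_fc**2))
            # gradient vanishes only in degenerate direction; leave dZ untouched
        else:
            r = 1.0 / mu
            D = np.maximum(q[:, None] + q[None, :] - 2.0 * (Z @ Z.T), 0.0)
            GS_prime = np.exp(-r * D)
            E = 2.0 * (GS_prime - GS)
            if fc_mask is not None:
                E = E * fc_mask
            P = E * GS_prime
            L_fc = float(0.5 * np.sum(E * (GS_prime - GS)))
            grad_D = -4.0 * r * (P.sum(axis=1)[:, None] * Z - P @ Z)
            c = float(np.sum(P * D))
            grad_r = (2.0 * c / (m * mu * mu)) * Z
            dZ = dZ + config.lambda1 * (grad_D + grad_r)

    # --- difference prompt
    L_mp = 0.0
    dD_L = np.zeros_like(params.D_L)
    if config.use_difference_prompt and pseudo_labels is not None:
        L_mp, dZ_mp, dD_L_mp = _difference_prompt_loss_grads(
            Z, pseudo_labels, params.D_L, config.tau, config.normalize_discriminator
        )
        dZ = dZ + config.lambda2 * dZ_mp
        dD_L = config.lambda2 * dD_L_mp

    # --- backprop through the encoder
    dW1 = AH.T @ dZ
    dH = (A_hat @ dZ) @ params.W1.T        # A_hat is symmetric
    dH0 = dH * _elu_grad(H0)
    dW0 = AX.T @ dH0

    L_total = total_loss(
        (L_rec, L_fc, L_mp),
        config.lambda1,
        config.lambda2,
        config.use_knowledge,
        config.use_difference_prompt,
    )
    losses = {"L_rec": L_rec, "L_fc": L_fc, "L_mp": L_mp, "L_total": L_total, "Z": Z}
    grads = {"W0": dW0, "W1": dW1, "D_L": dD_L}
    return losses, grads


class _Adam:
    def __init__(self, shapes: dict[str, tuple], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sample_entries(A: np.ndarray, ratio: float, rng: np.random.Generator):
    """Positive upper-triangle entries plus sampled non-edge entries."""
    iu, ju = np.triu_indices(A.shape[0], k=1)
    pos = A[iu, ju] > 0
    pr, pc = iu[pos], ju[pos]
    nr, nc = iu[~pos], ju[~pos]
    n_pos = len(pr)
    if n_pos == 0:
        return None
    n_neg = min(int(round(ratio * n_pos)), len(nr))
    sel = rng.choice(len(nr), size=n_neg, replace=False)
    rows = np.concatenate([pr, nr[sel]])
    cols = np.concatenate([pc, nc[sel]])
    return rows, cols


def train(
    net: CooperationNetwork,
    knowledge: KnowledgeTable | None,
    data: ExpressionDataset,
    config: RunConfig,
) -> tuple[GAEParameters, LatentRepresentation, TrainingTrace]:
    """Train the auto-encoder on the cooperation network.

    Deterministic: identical inputs, config and seed give a bit-identical
    trace.  Non-finite loss aborts with the epoch index.
    """
    A = net.graph.weights
    A_bin = (A > 0).astype(float)
    A_hat = normalized_adjacency(A_bin)
    X = net.attributes
    params = init_parameters(X.shape[1], config.hidden_dims, config.discriminator_dim, config.seed)

    GS = None
    fc_mask = None
    if config.use_knowledge:
        if knowledge is None:
            raise ValueError("use_knowledge=True requires a knowledge table")
        GS = knowledge_similarity(knowledge.assoc)
    pseudo = assign_pseudo_labels(data, config.t_test_variant) if config.use_difference_prompt else None

    rng = np.random.default_rng(config.seed + 1)
    use_sampling = config.negative_sampling and A_bin.sum() > 0
    if config.negative_sampling and A_bin.sum() == 0:
        logger.info("graph has no edges; falling back to full-matrix reconstruction loss")

    pdict = {"W0": params.W0, "W1": params.W1, "D_L": params.D_L}
    opt = _Adam({k: v.shape for k, v in pdict.items()}, lr=config.learning_rate)
    trace = {k: np.zeros(config.epochs) for k in ("L_rec", "L_fc", "L_mp", "L_total")}

    for epoch in range(config.epochs):
        entries = _sample_entries(A_bin, config.neg_sample_ratio, rng) if use_sampling else None
        losses, grads = _objective_and_grads(
            params, A_hat, X, A_bin, GS, pseudo, config, entries, fc_mask
        )
        if not np.isfinite(losses["L_total"]):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        for k in trace:
            trace[k][epoch] = losses[k]
        opt.step(pdict, grads)

    Z = encode(A_hat, X, params)
    return (
        params,
        LatentRepresentation(Z=Z, node_ids=list(net.graph.node_ids)),
        TrainingTrace(seed=config.seed, **{k: v for k, v in trace.items()}),
    )


def build_enhanced_network(
    Z: np.ndarray | LatentRepresentation,
    node_ids: list[str] | None = None,
    theta: float = 0.5,
    restrict_to: WeightedGraph | None = None,
) -> WeightedGraph:
    """Derive the enhanced weighted graph from decoder probabilities.

    An edge (i, j) is kept iff sigmoid(Z_i . Z_j) >= theta; kept edges
    carry that probability as weight.  Isolated nodes stay in the graph.

    With ``restrict_to`` (the recommended mode, used by the pipeline)
    only edges already present in the given cooperation network are
    eligible: the enhancement step's purpose is to mitigate false
    positives among the data-driven edges, and reweighting + pruning the
    observed topology does exactly that, whereas an unrestricted
    threshold can introduce brand-new edges the expression data never
    proposed.
    """
    if isinstance(Z, LatentRepresentation):
        node_ids = Z.node_ids if node_ids is None else node_ids
        Z = Z.Z
    if node_ids is None:
        raise ValueError("node_ids required when Z is a bare array")
    W = decode(np.asarray(Z, dtype=float))
    W = np.where(W >= theta, W, 0.0)
    np.fill_diagonal(W, 0.0)
    if restrict_to is not None:
        if restrict_to.node_ids != list(node_ids):
            raise ValueError("restriction graph nodes differ from latent node order")
        W = np.where(restrict_to.weights > 0, W, 0.0)
    return WeightedGraph(node_ids=list(node_ids), weights=W)
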