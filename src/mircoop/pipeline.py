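"""End-to-end orchestration and the repeated cross-validation harness."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

import mircoop
from mircoop.config import RunConfig
from mircoop.coop import build_cooperation_network
from mircoop.gae import build_enhanced_network, train
from mircoop.io import (
    ExpressionDataset,
    KnowledgeTable,
    WeightedGraph,
    write_graph,
    write_modules,
)
from mircoop.modules import ModuleSet, VotingEnsemble, find_modules, fit_ensemble, predict, select_top_k

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Confusion counts per (repeat, fold) and percent summary statistics."""

    folds: list[dict]  # each: repeat, fold, tp, fp, tn, fn

    @staticmethod
    def _metrics(c: dict) -> tuple[float, float, float]:
        tp, fp, tn, fn = c["tp"], c["fp"], c["tn"], c["fn"]
        acc = 100.0 * (tp + tn) / max(tp + tn + fp + fn, 1)
        sens = 100.0 * tp / max(tp + fn, 1)
        spec = 100.0 * tn / max(tn + fp, 1)
        return acc, sens, spec

    def summary(self) -> dict:
        rows = np.array([self._metrics(c) for c in self.folds])
        out = {}
        for i, name in enumerate(("accuracy", "sensitivity", "specificity")):
            out[f"{name}_mean"] = float(rows[:, i].mean())
            out[f"{name}_sd"] = float(rows[:, i].std(ddof=1)) if len(rows) > 1 else 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.folds)


def run_pipeline(
    data: ExpressionDataset,
    knowledge: KnowledgeTable | None,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> tuple[ModuleSet, VotingEnsemble, dict]:
    """Cooperation network → auto-encoder enhancement → module search → ensemble.

    Runs on the given (training) samples only.  With ``use_gae=False``
    the module search runs directly on the binary cooperation network
    (unit edge weights).  Artifacts are persisted when ``out_dir`` is
    given.
    """
    net = build_cooperation_network(data, knowledge, config)
    artifacts: dict = {"cooperation_network": net}

    if config.use_gae:
        params, latent, trace = train(net, knowledge, data, config)
        graph = build_enhanced_network(
            latent,
            theta=config.edge_threshold,
            restrict_to=net.graph if config.gnet_restrict_to_coop else None,
        )
        artifacts.update({"gae_parameters": params, "latent": latent, "trace": trace})
    else:
        graph = WeightedGraph(
            node_ids=list(net.graph.node_ids), weights=(net.graph.weights > 0).astype(float)
        )
    artifacts["enhanced_network"] = graph

    rng = np.random.default_rng(config.seed + 2)
    modules = find_modules(graph, data, config, rng)
    top = select_top_k(modules, config.k) if len(modules) else modules
    if len(top) == 0:
        raise ValueError("no modules found; the graph has no edges")
    ensemble = fit_ensemble(data, top, config)
    artifacts["all_modules"] = modules

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_graph(net.graph, out / "cooperation_network.tsv")
        write_graph(graph, out / "enhanced_network.tsv")
        write_modules(top, out / "modules.gmt")
        if config.use_gae:
            np.savetxt(out / "latent.tsv", artifacts["latent"].Z, delimiter="\t")
            tr = artifacts["trace"]
            pd.DataFrame(
                {"L_rec": tr.L_rec, "L_fc": tr.L_fc, "L_mp": tr.L_mp, "L_total": tr.L_total}
            ).to_csv(out / "loss_trace.tsv", sep="\t", index_label="epoch")
        (out / "manifest.json").write_text(json.dumps(make_manifest(data, knowledge, config), indent=2))
    return top, ensemble, artifacts


def cross_validate(
    data: ExpressionDataset,
    knowledge: KnowledgeTable | None,
    config: RunConfig,
    folds: int = 10,
    repeats: int = 10,
) -> EvaluationReport:
    """Repeated stratified k-fold evaluation of the full pipeline.

    The entire pipeline — network, auto-encoder, module search, ensemble
    — is refit on each training split; confusion counts come from the
    held-out fold only, so no test information reaches any fitting
    stage.  Folds are reduced when the smaller class cannot fill them.
    """
    y = data.labels
    min_class = int(min(np.sum(y == 0), np.sum(y == 1)))
    n_folds = min(folds, min_class)
    if n_folds < folds:
        logger.warning("reduced folds from %d to %d (smallest class)", folds, n_folds)

    fixed_modules = None
    if not config.refit_per_fold:
        # fidelity mode: discover modules once on all samples, refit only the
        # per-module SVMs inside each fold (module discovery then sees test
        # samples — documented leakage, off by default)
        fixed_modules, _, _ = run_pipeline(data, knowledge, config)

    records = []
    for rep in range(repeats):
        rep_seed = (config.seed + 1000 * rep + 1) % (2**31)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        for fold, (tr_idx, te_idx) in enumerate(skf.split(data.values, y)):
            train_data = data.subset_samples(tr_idx)
            test_data = data.subset_samples(te_idx)
            if fixed_modules is not None:
                ensemble = fit_ensemble(train_data, fixed_modules, config)
            else:
                cfg = config.replace(seed=rep_seed + fold)
                _, ensemble, _ = run_pipeline(train_data, knowledge, cfg)
            pred, _ = predict(ensemble, test_data)
            truth = test_data.labels
            records.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "tp": int(np.sum((pred == 1) & (truth == 1))),
                    "fp": int(np.sum((pred == 1) & (truth == 0))),
                    "tn": int(np.sum((pred == 0) & (truth == 0))),
                    "fn": int(np.sum((pred == 0) & (truth == 1))),
                }
            )
    return EvaluationReport(folds=records)


def make_manifest(
    data: ExpressionDataset, knowledge: KnowledgeTable | None, config: RunConfig
) -> dict:
    """Reproducibility stamp: config hash, seed, versions, input checksums."""

    def checksum(arr: np.ndarray) -> str:
        return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]

    return {
        "package_version": mircoop.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "expression_checksum": checksum(data.values),
        "labels_checksum": checksum(data.labels),
        "knowledge_checksum": checksum(knowledge.assoc) if knowledge is not None else None,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
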