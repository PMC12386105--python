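"""Run configuration: every tunable of the pipeline, with defaults.

Defaults follow the published protocol for this method: lambda1 = 0.1,
lambda2 = 1e-7, Maxmodulenum = 10, learning rate 0.01, 200 epochs,
temperature tau = 0.1 and k = 7 selected modules.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # cooperation network
    p_edge: float = 0.05                 # t-test edge threshold on f_com
    svm_C: float = 1.0                   # soft-margin C, pairwise and ensemble SVMs
    t_test_variant: str = "welch"        # "welch" | "student"
    standardize: bool = True             # z-score features before every SVM fit
    variance_prefilter: float = 0.0      # drop pairs whose pooled variance is below this (0 = off)

    # graph auto-encoder
    lambda1: float = 0.1                 # weight of the functional-consistency loss
    lambda2: float = 1e-7                # weight of the difference-prompt loss
    learning_rate: float = 0.01
    epochs: int = 200
    tau: float = 0.1                     # contrastive temperature
    hidden_dims: tuple[int, int] = (64, 32)
    discriminator_dim: int = 16
    normalize_discriminator: bool = True # L2-normalize D_L outputs before the dot product
    neg_sample_ratio: float = 1.0        # negatives per positive for the reconstruction loss
    negative_sampling: bool = True
    edge_threshold: float = 0.5          # theta: decoder probability cut for the enhanced network
    gnet_restrict_to_coop: bool = True   # prune within the observed topology (no brand-new edges)

    # module search
    max_modules: int = 10                # Maxmodulenum
    k: int = 7                           # modules kept for the voting ensemble
    auc_mode: str = "cv"                 # "cv" | "resubstitution"
    auc_folds: int = 5

    # ablation switches
    use_knowledge: bool = True
    use_difference_prompt: bool = True
    use_gae: bool = True

    # evaluation
    refit_per_fold: bool = True

    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be nonnegative")
        if not 0 < self.p_edge < 1:
            raise ValueError("p_edge must lie in (0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.k > self.max_modules:
            raise ValueError("k cannot exceed max_modules")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.t_test_variant not in ("welch", "student"):
            raise ValueError("t_test_variant must be 'welch' or 'student'")
        if self.auc_mode not in ("cv", "resubstitution"):
            raise ValueError("auc_mode must be 'cv' or 'resubstitution'")
        self.hidden_dims = tuple(self.hidden_dims)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**raw)
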