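"""Probe-level preprocessing: collapse probes onto miRNA accessions.

Microarray platforms report probes, not mature miRNAs.  The collapse
rules are: (1) a probe annotated with more than one distinct accession is
ambiguous and removed; (2) among probes annotated with the same single
accession, only the probe with the highest mean expression across all
samples is kept; (3) probes with no annotation at all are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from mircoop.io import ExpressionDataset, MappingTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ProbeMatrix:
    """Raw probes × samples expression before identifier mapping."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # n samples × n_probes
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("probe matrix contains missing values")


@dataclass
class PreprocessReport:
    input_probes: int
    removed_multimapped: int
    removed_unmapped: int
    duplicates_discarded: int
    retained: int

    def __post_init__(self) -> None:
        total = (
            self.removed_multimapped
            + self.removed_unmapped
            + self.duplicates_discarded
            + self.retained
        )
        assert total == self.input_probes, "probe counts do not conserve"


def _partition(probes: ProbeMatrix, mapping: MappingTable):
    """Split probes into (kept probe index per accession, removal counters)."""
    acc_map = mapping.as_dict()
    multimapped, unmapped = [], []
    by_accession: dict[str, list[int]] = {}
    for idx, probe in enumerate(probes.probe_ids):
        accs = acc_map.get(probe)
        if accs is None:
            unmapped.append(idx)
        elif len(set(accs)) > 1:
            multimapped.append(idx)
        else:
            by_accession.setdefault(accs[0], []).append(idx)

    means = probes.values.mean(axis=0)
    kept: dict[str, int] = {}
    duplicates = 0
    for acc, idxs in by_accession.items():
        best = max(idxs, key=lambda i: (means[i], -i))  # tie -> first in input order
        if len(idxs) > 1:
            duplicates += len(idxs) - 1
            tied = [i for i in idxs if means[i] == means[best] and i != best]
            if tied:
                logger.info(
                    "mean tie collapsing to %s: kept first-in-file probe %s",
                    acc, probes.probe_ids[best],
                )
        kept[acc] = best
    return kept, multimapped, unmapped, duplicates


def collapse_probes(probes: ProbeMatrix, mapping: MappingTable) -> ExpressionDataset:
    """Apply the collapse rules and rename surviving probes to accessions.

    Raises if no probe survives.  Output feature order follows the input
    order of the kept probes.
    """
    kept, _, _, _ = _partition(probes, mapping)
    if not kept:
        raise ValidationError("no probe survives mapping/collapse")
    order = sorted(kept.items(), key=lambda kv: kv[1])
    accs = [acc for acc, _ in order]
    cols = [i for _, i in order]
    return ExpressionDataset(
        feature_ids=accs,
        sample_ids=list(probes.sample_ids),
        values=probes.values[:, cols],
        labels=probes.labels,
    )


def preprocess_report(probes: ProbeMatrix, mapping: MappingTable) -> PreprocessReport:
    kept, multimapped, unmapped, duplicates = _partition(probes, mapping)
    return PreprocessReport(
        input_probes=len(probes.probe_ids),
        removed_multimapped=len(multimapped),
        removed_unmapped=len(unmapped),
        duplicates_discarded=duplicates,
        retained=len(kept),
    )
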