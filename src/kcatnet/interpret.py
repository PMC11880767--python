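"""Residue-level importance from the structure stream.

The per-residue output vectors of the protein GCN are reduced to a scalar
(their Euclidean norm) and min-max normalised to [0, 1]; these weight
scores rank residues by how strongly the structure stream represents them.
The top fraction of residues (5% by default) is compared against annotated
binding/active sites, either by direct overlap or by contact-map adjacency,
and score distributions of annotated versus general sites are contrasted
with a two-sided t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import AnnotationError, InputError
from .features import FeaturizedRecord
from .network import KcatNetwork
from .structure import ContactMap, ProteinStructure, write_structure
from .training import compare_groups

__all__ = [
    "ResidueWeights",
    "SiteAnnotation",
    "HitRateResult",
    "residue_weight_scores",
    "top_fraction_sites",
    "site_group_comparison",
    "hit_rate",
    "read_annotation",
    "write_weights_table",
    "write_weights_pdb",
]

BINDING_ACTIVE = "binding_active"
GENERAL = "general"


def minmax_normalize(raw: np.ndarray) -> np.ndarray:
    """(raw − min)/(max − min); all zeros when raw is constant."""
    raw = np.asarray(raw, dtype=float)
    span = raw.max() - raw.min()
    if span == 0.0:
        return np.zeros_like(raw)
    return (raw - raw.min()) / span


@dataclass
class ResidueWeights:
    """Min-max-normalised per-residue importance scores.

    ``residue_index`` is 1-based. Unless the raw norms are constant,
    min(scores) == 0 and max(scores) == 1; the all-constant degenerate case
    maps every score to 0.
    """

    scores: np.ndarray
    raw_norms: np.ndarray
    residue_index: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class SiteAnnotation:
    """residue_index (1-based) → label, binding/active vs general."""

    labels: dict[int, str]
    n_residues: int

    def __post_init__(self) -> None:
        for index, label in self.labels.items():
            if not 1 <= index <= self.n_residues:
                raise AnnotationError(
                    f"annotated residue {index} outside [1, {self.n_residues}]"
                )
            if label not in (BINDING_ACTIVE, GENERAL):
                raise AnnotationError(f"unknown site label {label!r}")

    def binding_active_sites(self) -> set[int]:
        return {i for i, l in self.labels.items() if l == BINDING_ACTIVE}

    def label_of(self, index: int) -> str:
        return self.labels.get(index, GENERAL)


@dataclass
class HitRateResult:
    """Fraction of high-weight sites that hit annotated sites."""

    value: float
    mode: str  # "direct" or "adjacency"
    n_high_weight: int
    n_hits: int


def residue_weight_scores(network: KcatNetwork, feat: FeaturizedRecord) -> ResidueWeights:
    """Weight scores from the structure stream of a (trained) network.

    Raw per-residue scalars are the L2 norms of the final protein-GCN
    output vectors; scores are (raw − min)/(max − min), or all zero when
    the raw norms are constant.
    """
    if feat.contact_adjacency is None or feat.residue_type_ids is None:
        raise InputError(
            f"record {feat.record_id!r} has no structure features; "
            "weight scores need the structure stream"
        )
    nodes = network.protein_node_features(
        feat.residue_type_ids,
        feat.contact_adjacency,
        propagator=feat.protein_propagator,
    ).numpy()
    raw = np.linalg.norm(nodes, axis=1)
    scores = minmax_normalize(raw)
    return ResidueWeights(
        scores=scores,
        raw_norms=raw,
        residue_index=np.arange(1, len(raw) + 1),
    )


def top_fraction_sites(weights: ResidueWeights, fraction: float = 0.05) -> list[int]:
    """The ceil(fraction · N) residues with the highest weight scores.

    Ties at the cutoff are broken toward the lower residue index; the
    result is sorted ascending by residue index.
    """
    if not 0.0 < fraction <= 1.0:
        raise InputError(f"fraction must be in (0, 1], got {fraction}")
    n = len(weights)
    k = math.ceil(fraction * n)
    order = sorted(range(n), key=lambda i: (-weights.scores[i], i))
    chosen = sorted(int(weights.residue_index[i]) for i in order[:k])
    return chosen


def site_group_comparison(
    weights: ResidueWeights, annotation: SiteAnnotation
) -> tuple[float, float, dict[str, float]]:
    """t-test of weight scores: binding/active sites vs general sites.

    Returns ``(t, two_sided_p, group_means)``.
    """
    binding = [
        float(weights.scores[i - 1])
        for i in annotation.binding_active_sites()
    ]
    general = [
        float(weights.scores[int(idx) - 1])
        for idx in weights.residue_index
        if annotation.label_of(int(idx)) == GENERAL
    ]
    if not binding or not general:
        raise AnnotationError("both binding/active and general groups must be non-empty")
    t, p = compare_groups(binding, general)
    means = {
        BINDING_ACTIVE: float(np.mean(binding)),
        GENERAL: float(np.mean(general)),
    }
    return t, p, means


def hit_rate(
    high_weight: Sequence[int],
    annotation: SiteAnnotation,
    contact_map: ContactMap | None = None,
) -> HitRateResult:
    """Fraction of high-weight sites that coincide with annotated sites.

    In direct mode a hit is a high-weight site annotated binding/active; in
    adjacency mode (a contact map supplied) a contact neighbour of an
    annotated site also counts. The mode used is recorded in the result.
    """
    high = sorted(set(int(i) for i in high_weight))
    if not high:
        raise AnnotationError("high-weight site set is empty; hit rate undefined")
    for index in high:
        if not 1 <= index <= annotation.n_residues:
            raise AnnotationError(
                f"high-weight residue {index} outside [1, {annotation.n_residues}]"
            )
    annotated = annotation.binding_active_sites()

    def is_hit(index: int) -> bool:
        if index in annotated:
            return True
        if contact_map is not None:
            neighbors = np.nonzero(contact_map.adjacency[index - 1])[0] + 1
            return any(int(j) in annotated for j in neighbors)
        return False

    hits = sum(1 for i in high if is_hit(i))
    return HitRateResult(
        value=hits / len(high),
        mode="adjacency" if contact_map is not None else "direct",
        n_high_weight=len(high),
        n_hits=hits,
    )


def read_annotation(path: str | Path, n_residues: int) -> SiteAnnotation:
    """Read a 2-column TSV (residue_index, label) site annotation."""
    labels: dict[int, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            index_str, label = line.split("\t")[:2]
            labels[int(index_str)] = label
    return SiteAnnotation(labels=labels, n_residues=n_residues)


def write_weights_table(
    weights: ResidueWeights,
    path: str | Path,
    high_weight: Sequence[int] | None = None,
) -> None:
    """TSV export: residue_index, raw_norm, score, is_high_weight."""
    high = set(high_weight or ())
    with open(path, "w") as handle:
        handle.write("residue_index\traw_norm\tscore\tis_high_weight\n")
        for idx, raw, score in zip(weights.residue_index, weights.raw_norms, weights.scores):
            handle.write(f"{int(idx)}\t{raw:.6f}\t{score:.6f}\t{int(int(idx) in high)}\n")


def write_weights_pdb(
    structure: ProteinStructure, weights: ResidueWeights, path: str | Path
) -> None:
    """Write the structure with weight scores in the B-factor column.

    Standard structure viewers can then colour residues by score.
    """
    if len(structure) != len(weights):
        raise InputError(
            f"structure has {len(structure)} residues but weights cover {len(weights)}"
        )
    painted = ProteinStructure(
        residue_ids=structure.residue_ids,
        sequence=structure.sequence,
        ca_coords=structure.ca_coords,
        chain_id=structure.chain_id,
        plddt=np.asarray(weights.scores, dtype=float) * 100.0,
    )
    write_structure(painted, path)
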