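"""Reference-tree network similarity: placing subjects on a two-anchor
disease spectrum.

Two reference MSTs are built from group-averaged connectivity — one for
each anchor group (pure-motor ALS and bvFTD).  Each scored subject's
per-epoch MSTs are compared with a reference by edge overlap (fraction of
the N-1 tree edges present in both), and the per-epoch overlaps averaged.
The difference sim(bvFTD ref) - sim(motor ref) locates the subject between
the anchors.

An alternative mode first averages the subject's epoch adjacency matrices
and overlaps the single MST of that mean matrix with the reference; it
trades epoch-level noise for a single, more stable tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix, epoch_average
from .errors import ConsistencyError
from .mst import SpanningTree, mst_from_connectivity

__all__ = [
    "ReferenceTree",
    "SimilarityScore",
    "reference_mst",
    "edge_overlap",
    "subject_similarity",
    "subject_similarity_mean_adjacency",
]


@dataclass
class ReferenceTree:
    """Anchor-group MST for one band and timepoint."""

    label: str          # "motor" or "bvftd"
    band: str
    timepoint: str
    tree: SpanningTree

    def __post_init__(self):
        if self.label not in ("motor", "bvftd"):
            raise ConsistencyError(
                f"reference label must be 'motor' or 'bvftd', got {self.label!r}"
            )


@dataclass
class SimilarityScore:
    subject_id: str
    band: str
    timepoint: str
    reference: str      # "motor" or "bvftd"
    value: float
    mode: str           # "per_epoch_mean" or "mean_adjacency"

    def __post_init__(self):
        if not (0.0 <= self.value <= 1.0):
            raise ConsistencyError("similarity must lie in [0, 1]")
        if self.mode not in ("per_epoch_mean", "mean_adjacency"):
            raise ConsistencyError(f"unknown mode {self.mode!r}")


def reference_mst(group_matrices: list[ConnectivityMatrix], label: str,
                  band: str = "", timepoint: str = "") -> ReferenceTree:
    """MST of the unweighted mean of the group's per-subject epoch-mean
    connectivity matrices (each subject contributes equally)."""
    if not group_matrices:
        raise ConsistencyError("reference group is empty")
    mean = epoch_average(group_matrices, provenance="group_mean")
    tree = mst_from_connectivity(mean)
    return ReferenceTree(label=label, band=band or mean.band,
                         timepoint=timepoint, tree=tree)


def edge_overlap(a: SpanningTree, b: SpanningTree) -> float:
    """Fraction of the N-1 edges present in both trees, in [0, 1].

    Edges are compared as unordered ROI-label pairs, so trees built from
    differently ordered inputs compare correctly.
    """
    if a.n_nodes != b.n_nodes:
        raise ConsistencyError("trees have different node counts")
    if set(a.roi_labels) != set(b.roi_labels):
        raise ConsistencyError("trees have different node label sets")
    shared = a.edge_label_pairs() & b.edge_label_pairs()
    return len(shared) / (a.n_nodes - 1)


def subject_similarity(subject_epoch_trees: list[SpanningTree],
                       ref: ReferenceTree,
                       subject_id: str = "") -> SimilarityScore:
    """Mean over epochs of the edge overlap with the reference tree."""
    if not subject_epoch_trees:
        raise ConsistencyError("need at least one epoch tree")
    overlaps = [edge_overlap(t, ref.tree) for t in subject_epoch_trees]
    return SimilarityScore(subject_id=subject_id, band=ref.band,
                           timepoint=ref.timepoint, reference=ref.label,
                           value=float(np.mean(overlaps)),
                           mode="per_epoch_mean")


def subject_similarity_mean_adjacency(
        subject_epoch_matrices: list[ConnectivityMatrix],
        ref: ReferenceTree, subject_id: str = "") -> SimilarityScore:
    """Overlap of the MST of the subject's mean adjacency matrix with the
    reference tree (single comparison, no per-epoch averaging)."""
    if not subject_epoch_matrices:
        raise ConsistencyError("need at least one epoch matrix")
    mean = epoch_average(subject_epoch_matrices)
    tree = mst_from_connectivity(mean)
    return SimilarityScore(subject_id=subject_id, band=ref.band,
                           timepoint=ref.timepoint, reference=ref.label,
                           value=edge_overlap(tree, ref.tree),
                           mode="mean_adjacency")
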