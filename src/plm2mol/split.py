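"""Similarity-constrained protein-level train/test splitting.

Proteins are first grouped into single-linkage clusters of the graph
whose edges connect pairs with Needleman-Wunsch global-alignment
similarity at or above the threshold (default 80%).  Whole clusters are
then assigned to the training or test side by a seeded randomized
greedy packing that targets the requested fraction of interaction
PAIRS (default two-thirds) in training.  Assigning clusters whole
guarantees that every cross-set protein pair falls below the threshold.

Similarity between two sequences is the maximum number of identically
aligned residues under global alignment (match +1, mismatch 0, gaps 0),
normalized by the longer sequence length and expressed in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .decoder import ProteinRecord

__all__ = [
    "SplitSpec",
    "global_similarity",
    "similarity_clusters",
    "make_split",
    "DEFAULT_SIMILARITY_THRESHOLD",
    "DEFAULT_TRAIN_FRACTION",
]

DEFAULT_SIMILARITY_THRESHOLD = 80.0
DEFAULT_TRAIN_FRACTION = 2.0 / 3.0

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SplitSpec:
    """A protein-level split with its constraint and provenance."""

    train_proteins: frozenset[str]
    test_proteins: frozenset[str]
    threshold_pct: float
    seed: int
    achieved_train_fraction: float

    def __post_init__(self) -> None:
        if self.train_proteins & self.test_proteins:
            raise ValueError("train and test protein sets must be disjoint")


def _make_aligner(
    match: float = 1.0, mismatch: float = 0.0, gap: float = 0.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def global_similarity(
    seq_a: str, seq_b: str, aligner: Optional[Align.PairwiseAligner] = None
) -> float:
    """Percent global-alignment similarity between two protein sequences.

    With identity scoring the optimal alignment score equals the maximum
    number of identical aligned positions; similarity is that count over
    the longer sequence length, times 100.  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    for name, seq in (("a", seq_a), ("b", seq_b)):
        bad = set(seq) - _AA
        if bad:
            raise ValueError(
                f"sequence {name} contains non-amino-acid letters: {sorted(bad)}"
            )
    if aligner is None:
        aligner = _make_aligner()
    score = aligner.score(seq_a, seq_b)
    return 100.0 * float(score) / max(len(seq_a), len(seq_b))


def similarity_clusters(
    proteins: Sequence[ProteinRecord],
    threshold_pct: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> dict[str, int]:
    """Single-linkage components of the >=threshold similarity graph."""
    missing = [p.id for p in proteins if not p.sequence]
    if missing:
        raise ValueError(f"proteins missing sequences: {missing}")
    n = len(proteins)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    aligner = _make_aligner()
    for i in range(n):
        for j in range(i + 1, n):
            sim = global_similarity(
                proteins[i].sequence, proteins[j].sequence, aligner
            )
            if sim >= threshold_pct:
                parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for i, p in enumerate(proteins):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        labels[p.id] = roots[r]
    return labels


def make_split(
    proteins: Sequence[ProteinRecord],
    pairs: Sequence,
    frac_train: float = DEFAULT_TRAIN_FRACTION,
    threshold_pct: float = DEFAULT_SIMILARITY_THRESHOLD,
    seed: int = 0,
) -> SplitSpec:
    """Assign similarity clusters whole to train/test, targeting
    ``frac_train`` of pairs in training.

    ``pairs`` is any sequence of objects with a ``protein_id`` attribute
    (or (protein_id, ...) tuples).  Reproducible given ``seed``.
    """
    labels = similarity_clusters(proteins, threshold_pct)

    def pid(pair) -> str:
        return pair.protein_id if hasattr(pair, "protein_id") else pair[0]

    pair_count: dict[int, int] = {}
    for pair in pairs:
        protein = pid(pair)
        if protein not in labels:
            raise ValueError(f"pair references unknown protein {protein!r}")
        cluster = labels[protein]
        pair_count[cluster] = pair_count.get(cluster, 0) + 1
    clusters = sorted(pair_count)
    total = sum(pair_count.values())
    if len(clusters) < 2:
        raise ValueError(
            f"split infeasible at threshold {threshold_pct}: "
            "a single similarity cluster spans every protein with pairs"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))
    target = frac_train * total
    train_clusters: set[int] = set()
    train_pairs = 0
    for k in order:
        cluster = clusters[k]
        size = pair_count[cluster]
        # greedy: add to train when that moves the train pair count
        # closer to the target than leaving it out
        if abs(train_pairs + size - target) <= abs(train_pairs - target):
            train_clusters.add(cluster)
            train_pairs += size
    if not train_clusters or len(train_clusters) == len(clusters):
        # degenerate greedy outcome: force at least one cluster per side
        first = clusters[order[0]]
        if not train_clusters:
            train_clusters.add(first)
            train_pairs += pair_count[first]
        else:
            train_clusters.discard(first)
            train_pairs -= pair_count[first]

    train_ids = frozenset(p.id for p in proteins if labels[p.id] in train_clusters)
    test_ids = frozenset(p.id for p in proteins) - train_ids
    return SplitSpec(
        train_proteins=train_ids,
        test_proteins=frozenset(test_ids),
        threshold_pct=threshold_pct,
        seed=seed,
        achieved_train_fraction=train_pairs / total,
    )
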