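"""Drug-target interaction evaluation statistics.

Consumes externally predicted DTI scores for (protein, molecule) pairs
and provides the evaluation protocol around them: per-protein positive
and negative pair-set construction, AUC with a one-sided Mann-Whitney
test, Benjamini-Hochberg FDR control across proteins, one-sided Fisher
enrichment of positives above a fixed score threshold (default 0.923,
the high-precision operating point of the upstream predictor), Pearson
correlation of paired AUC vectors, and mining of generated molecules
that exactly reproduce known ligands (proper hits for the generating
protein, repurposed triples for other proteins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairSets",
    "StatResult",
    "ReproducedHit",
    "assemble_pair_sets",
    "auc_mannwhitney",
    "bh_fdr",
    "enrichment_fisher",
    "auc_correlation",
    "mine_reproduced",
    "DEFAULT_SCORE_THRESHOLD",
    "MIN_KNOWN_LIGANDS",
]

#: score threshold for the enrichment analysis (high-precision screen)
DEFAULT_SCORE_THRESHOLD = 0.923

#: comparisons against known binders are restricted to proteins with at
#: least this many known ligands
MIN_KNOWN_LIGANDS = 10


@dataclass(frozen=True)
class PairSets:
    """Equal-sized molecule sets for the per-protein comparisons.

    For a protein A: ``pos_g`` are the new molecules generated for A;
    ``neg_g`` molecules generated for other proteins; ``neg_d`` known
    ligands of other proteins; ``true_pos`` known binders of A.  The
    negative sets exclude every molecule associated with A.
    """

    protein_id: str
    pos_g: tuple[str, ...]
    neg_g: tuple[str, ...]
    neg_d: tuple[str, ...]
    true_pos: tuple[str, ...]
    seed: int


@dataclass(frozen=True)
class StatResult:
    """AUC / p-value outcome of one pair-set comparison."""

    protein_id: str
    comparison: str
    auc: float
    p_one_sided: float
    n_pos: int
    n_neg: int
    significant_at_fdr: Optional[bool] = None


@dataclass(frozen=True)
class ReproducedHit:
    """A generated molecule that matches a known interaction."""

    kind: str  # "proper" | "repurposed"
    source_protein: str
    smiles: str
    matched_protein: str

    def __post_init__(self) -> None:
        if self.kind == "proper" and self.matched_protein != self.source_protein:
            raise ValueError("proper hits must match the source protein")
        if self.kind == "repurposed" and self.matched_protein == self.source_protein:
            raise ValueError("repurposed hits must match a different protein")


def _canonical(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def assemble_pair_sets(
    protein_id: str,
    generated_by_protein: dict[str, Sequence[str]],
    known_pairs: Iterable[tuple[str, str]],
    seed: int = 0,
) -> PairSets:
    """Build the four comparison sets for one protein.

    Negative sets are sampled without replacement, seeded; all sets are
    down-sampled so every comparison is equal-sized against ``pos_g``.
    """
    if protein_id not in generated_by_protein:
        raise ValueError(f"no generated molecules for protein {protein_id!r}")
    if len(generated_by_protein) < 2:
        raise ValueError("pair-set construction needs molecules for >=2 proteins")

    known: dict[str, set[str]] = {}
    for pid, smiles in known_pairs:
        known.setdefault(pid, set()).add(smiles)
    own_molecules = set(generated_by_protein[protein_id]) | known.get(
        protein_id, set()
    )

    pos_g = list(dict.fromkeys(generated_by_protein[protein_id]))
    neg_g_pool = sorted(
        {
            s
            for pid, molecules in generated_by_protein.items()
            if pid != protein_id
            for s in molecules
        }
        - own_molecules
    )
    neg_d_pool = sorted(
        {
            s
            for pid, ligands in known.items()
            if pid != protein_id
            for s in ligands
        }
        - own_molecules
    )
    true_pos = sorted(known.get(protein_id, set()))

    rng = np.random.default_rng(seed)
    k = len(pos_g)

    def sample(pool: list[str], size: int) -> tuple[str, ...]:
        if len(pool) <= size:
            return tuple(pool)
        return tuple(rng.choice(pool, size=size, replace=False))

    return PairSets(
        protein_id=protein_id,
        pos_g=tuple(pos_g),
        neg_g=sample(neg_g_pool, k),
        neg_d=sample(neg_d_pool, k),
        true_pos=sample(true_pos, k),
        seed=seed,
    )


def equalize(a: Sequence, b: Sequence, seed: int = 0) -> tuple[tuple, tuple]:
    """Down-sample the larger of two sets so sizes match (seeded)."""
    rng = np.random.default_rng(seed)
    a, b = list(a), list(b)
    k = min(len(a), len(b))
    if len(a) > k:
        a = list(rng.choice(a, size=k, replace=False))
    if len(b) > k:
        b = list(rng.choice(b, size=k, replace=False))
    return tuple(a), tuple(b)


def auc_mannwhitney(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    alternative: str = "greater",
) -> tuple[float, float]:
    """AUC and one-sided Mann-Whitney p-value.

    AUC = U / (n_pos * n_neg) with ties credited 0.5.  The p-value uses
    exact enumeration when ``n_pos * n_neg <= 200`` and there are no
    ties, otherwise the tie-corrected normal approximation.  Identical
    constant scores on both sides return (0.5, 1.0) by convention.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    if np.ptp(np.concatenate([pos, neg])) == 0:
        return 0.5, 1.0
    has_ties = len(np.unique(np.concatenate([pos, neg]))) < pos.size + neg.size
    method = "exact" if (pos.size * neg.size <= 200 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(pos, neg, alternative=alternative, method=method)
    auc = float(res.statistic) / (pos.size * neg.size)
    return auc, float(res.pvalue)


def bh_fdr(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, Optional[float]]:
    """Benjamini-Hochberg step-up at level ``q``.

    Returns the rejection flags (in input order) and the largest
    rejected p-value (None when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else None
    return reject, threshold


def enrichment_fisher(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> tuple[float, float]:
    """One-sided Fisher exact test for enrichment of positive labels
    among scores at or above ``threshold``.

    Returns (odds ratio, p).  A degenerate 2x2 table (no scores above
    the threshold, or single-class labels) returns p = 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be the same length")
    above = scores >= threshold
    table = np.array(
        [
            [int(np.sum(above & (labels == 1))), int(np.sum(above & (labels == 0)))],
            [int(np.sum(~above & (labels == 1))), int(np.sum(~above & (labels == 0)))],
        ]
    )
    if table[0].sum() == 0 or table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return float("nan"), 1.0
    odds, p = sps.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def auc_correlation(
    auc_vector_1: Sequence[float], auc_vector_2: Sequence[float]
) -> tuple[Optional[float], Optional[float]]:
    """Pearson correlation (r, two-sided p) of two paired AUC vectors."""
    a = np.asarray(auc_vector_1, dtype=float)
    b = np.asarray(auc_vector_2, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("vectors must be paired with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None, None
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


def mine_reproduced(
    generated_by_protein: dict[str, Sequence[str]],
    known_pairs: Iterable[tuple[str, str]],
) -> tuple[list[ReproducedHit], dict[str, int]]:
    """Find generated molecules that reproduce known interactions.

    A *proper* hit is a molecule generated for protein A that is a known
    ligand of A itself; a *repurposed* triple (A, l, B) is a molecule
    generated for A that is a known ligand of a different protein B.
    Matching is on canonical SMILES.  Returns the hits and summary
    counts (distinct reproduced ligands, proper hits, repurposed
    triples).
    """
    ligand_to_proteins: dict[str, set[str]] = {}
    for pid, smiles in known_pairs:
        canon = _canonical(smiles)
        if canon is not None:
            ligand_to_proteins.setdefault(canon, set()).add(pid)

    hits: list[ReproducedHit] = []
    for source, molecules in generated_by_protein.items():
        unique = dict.fromkeys(
            c for s in molecules if (c := _canonical(s)) is not None
        )
        for canon in unique:
            for target in sorted(ligand_to_proteins.get(canon, ())):
                hits.append(
                    ReproducedHit(
                        kind="proper" if target == source else "repurposed",
                        source_protein=source,
                        smiles=canon,
                        matched_protein=target,
                    )
                )
    counts = {
        "distinct_ligands": len({h.smiles for h in hits}),
        "proper": sum(1 for h in hits if h.kind == "proper"),
        "repurposed": sum(1 for h in hits if h.kind == "repurposed"),
    }
    return hits, counts
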