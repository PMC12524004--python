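"""Synthetic desk-scale fixtures: molecule families, clustered protein
embeddings, interaction tables and analytic score distributions.

The generator emulates the structure of a curated interaction corpus at
a size where every component — curation, encoding, splitting, training,
sampling, metrics and statistics — can be exercised in seconds to
minutes on one CPU:

* molecule *families*: disjoint sets of valid, curation-clean SMILES
  enumerated from hand-written scaffolds by varying alkyl substituent
  lengths (whitelist elements only, lengths within the 24-95 window);
* *proteins*: each assigned to one family; its embedding is the family
  centroid (a spherical Gaussian draw) plus isotropic noise, so that
  family identity is linearly recoverable from the embedding — the
  desk-scale analogue of binding-site information in a PLM embedding;
* synthetic amino-acid *sequences*: per-family template sequences with
  per-protein point mutations, planting high within-family and low
  across-family global-alignment similarity for split tests;
* *scores*: positive scores ~ Normal(delta, 1) and negatives
  ~ Normal(0, 1), whose population AUC is the closed form
  Phi(delta / sqrt(2)).

The conditional-recovery experiment (:func:`conditional_recovery`)
trains a tiny decoder on such a fixture and measures, for a held-out
embedding of each family, the fraction of generated molecules belonging
to each family: target-conditioned generation at toy scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
from rdkit import Chem
from scipy.stats import norm

from . import codec
from .curation import InteractionPair
from .decoder import DecoderConfig, ParameterSet, ProteinRecord, train
from .sampler import generate_set

__all__ = [
    "FamilyLibrary",
    "EmbeddingFixture",
    "ScoreFixture",
    "make_family_library",
    "make_interaction_fixture",
    "make_score_fixture",
    "conditional_recovery",
]

# Scaffold templates: {a}/{b}/{c} are alkyl chains of 0-5 carbons, giving
# 216 enumerable members per scaffold.  All three use whitelist elements
# only, no stereocenters, no charges.
_SCAFFOLDS = (
    "CCOC(=O)N(CC{a})CCOCC{b}CNC(=O)CC{c}",
    "C{a}COc1ccc(CNC(=O)CC{b})cc1CC{c}c1ccc(Cl)cc1",
    "O=C(NC1CCN(CC{a})CC1)C{b}COCC{c}NC=O",
    "CC(C)(C{a})c1ccc(OCC{b}C(=O)NCC{c}F)cc1",
    "O=S(=O)(NCC{a})c1ccc(NC(=O)C{b}OC{c}C)cc1",
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilyLibrary:
    """Disjoint families of valid canonical SMILES."""

    families: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def family_of(self) -> dict[str, int]:
        return {s: f for f, members in enumerate(self.families) for s in members}

    @property
    def all_molecules(self) -> tuple[str, ...]:
        return tuple(s for members in self.families for s in members)


@dataclass(frozen=True)
class EmbeddingFixture:
    """Clustered protein embeddings with family assignments."""

    centroids: np.ndarray  # (n_families, d)
    embeddings: np.ndarray  # (n_proteins, d)
    family_of_protein: tuple[int, ...]
    sigma: float
    seed: int


@dataclass(frozen=True)
class ScoreFixture:
    """Two-sample normal score fixture with a known analytic AUC."""

    pos: np.ndarray
    neg: np.ndarray
    delta: float
    seed: int

    @property
    def analytic_auc(self) -> float:
        return float(norm.cdf(self.delta / np.sqrt(2.0)))


def make_family_library(
    n_families: int = 3, n_per_family: int = 200, seed: int = 0
) -> FamilyLibrary:
    """Enumerate ``n_per_family`` canonical molecules for each family.

    Members come from substituent grids on hand-written scaffolds, are
    canonicalized, and per family a seeded subset of the enumeration is
    kept.  Families are pairwise disjoint by construction (asserted).
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    if n_families > len(_SCAFFOLDS):
        raise ValueError(f"at most {len(_SCAFFOLDS)} families are available")
    rng = np.random.default_rng(seed)
    families: list[tuple[str, ...]] = []
    for f in range(n_families):
        members: list[str] = []
        for a, b, c in itertools.product(range(6), repeat=3):
            smiles = _SCAFFOLDS[f].format(a="C" * a, b="C" * b, c="C" * c)
            mol = Chem.MolFromSmiles(smiles)
            assert mol is not None, f"scaffold enumeration produced invalid {smiles!r}"
            members.append(Chem.MolToSmiles(mol))
        members = sorted(set(members))
        if n_per_family > len(members):
            raise ValueError(
                f"family {f}: requested {n_per_family} members, only "
                f"{len(members)} enumerable"
            )
        keep = rng.choice(len(members), size=n_per_family, replace=False)
        families.append(tuple(members[i] for i in sorted(keep)))
    seen: set[str] = set()
    for members in families:
        overlap = seen & set(members)
        assert not overlap, f"families share molecules: {sorted(overlap)[:3]}"
        seen |= set(members)
    return FamilyLibrary(families=tuple(families), seed=seed)


def _family_sequences(
    n_families: int, rng: np.random.Generator, length: int = 60
) -> list[str]:
    return [
        "".join(rng.choice(list(_AMINO_ACIDS), size=length))
        for _ in range(n_families)
    ]


def _mutate(seq: str, rng: np.random.Generator, rate: float = 0.05) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(list(_AMINO_ACIDS)))
    return "".join(out)


def make_interaction_fixture(
    library: FamilyLibrary,
    n_proteins_per_family: int = 10,
    sigma: float = 0.1,
    d: int = 64,
    seed: int = 0,
    with_sequences: bool = True,
) -> tuple[list[ProteinRecord], EmbeddingFixture, list[InteractionPair]]:
    """Proteins with clustered embeddings and their family's pairs.

    Each synthetic protein is assigned one family; its interaction pairs
    are all of that family's molecules; its embedding is the family
    centroid plus Normal(0, sigma) noise.  With ``with_sequences``,
    per-family template amino-acid sequences are point-mutated per
    protein, planting >=80% within-family similarity clusters.
    """
    rng = np.random.default_rng(seed)
    n_fam = library.n_families
    centroids = rng.normal(0.0, 1.0, size=(n_fam, d))
    base_seqs = _family_sequences(n_fam, rng) if with_sequences else None

    proteins: list[ProteinRecord] = []
    pairs: list[InteractionPair] = []
    family_of: list[int] = []
    embeddings = []
    for f in range(n_fam):
        for k in range(n_proteins_per_family):
            pid = f"P{f}_{k}"
            x = centroids[f] + rng.normal(0.0, sigma, size=d)
            seq = _mutate(base_seqs[f], rng) if with_sequences else None
            proteins.append(ProteinRecord(id=pid, embedding=x, sequence=seq))
            embeddings.append(x)
            family_of.append(f)
            for smiles in library.families[f]:
                pairs.append(InteractionPair(protein_id=pid, smiles=smiles))
    fixture = EmbeddingFixture(
        centroids=centroids,
        embeddings=np.asarray(embeddings),
        family_of_protein=tuple(family_of),
        sigma=sigma,
        seed=seed,
    )
    return proteins, fixture, pairs


def make_score_fixture(
    n_pos: int, n_neg: int, delta: float, seed: int = 0
) -> ScoreFixture:
    """Seeded normal score draws with analytic AUC = Phi(delta/sqrt(2))."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    rng = np.random.default_rng(seed)
    return ScoreFixture(
        pos=rng.normal(delta, 1.0, size=n_pos),
        neg=rng.normal(0.0, 1.0, size=n_neg),
        delta=delta,
        seed=seed,
    )


def conditional_recovery(
    seed: int = 0,
    n_families: int = 3,
    n_per_family: int = 200,
    n_proteins: int = 30,
    d: int = 32,
    sigma: float = 0.1,
    epochs: int = 25,
    n_generate: int = 40,
    n_heads: int = 2,
    pairs_per_protein: Optional[int] = None,
) -> dict:
    """Train a tiny decoder on the family fixture and measure how often
    sampling from a held-out embedding of family f recovers family-f
    molecules.

    Returns a dict with the trained parameters, the per-family fraction
    matrix ``fractions[f][g]`` (held-out family f, fraction of generated
    molecules belonging to family g), validity, and the loss history.
    """
    if n_proteins % n_families:
        raise ValueError("n_proteins must be divisible by n_families")
    library = make_family_library(n_families, n_per_family, seed=seed)
    proteins, fixture, pairs = make_interaction_fixture(
        library,
        n_proteins_per_family=n_proteins // n_families,
        sigma=sigma,
        d=d,
        seed=seed,
        with_sequences=False,
    )
    vocab = codec.build_default_vocabulary()
    max_len = max(len(s) for s in library.all_molecules)
    encoded = {
        s: codec.encode_smiles(s, max_raw_len=max_len, vocab=vocab)
        for s in library.all_molecules
    }
    by_id = {p.id: p for p in proteins}
    rng = np.random.default_rng(seed)
    if pairs_per_protein is not None:
        dataset = []
        for pid in by_id:
            own = [q for q in pairs if q.protein_id == pid]
            pick = rng.choice(len(own), size=min(pairs_per_protein, len(own)),
                              replace=False)
            dataset.extend((by_id[pid], encoded[own[i].smiles]) for i in pick)
    else:
        dataset = [(by_id[q.protein_id], encoded[q.smiles]) for q in pairs]

    config = DecoderConfig(
        n_layers=2,
        n_heads=n_heads,
        d_model=d,
        seq_len=max_len + 2,
        vocab_size=vocab.size,
        dropout=0.0,
        epochs=epochs,
        batch_size=200,
        learning_rate=0.001,
    )
    params, history = train(dataset, config, seed=seed, pad_id=vocab.pad_id)

    family_of = library.family_of
    fractions = np.zeros((n_families, n_families))
    validity = np.zeros(n_families)
    holdout_rng = np.random.default_rng(seed + 1)
    generated: dict[int, tuple[str, ...]] = {}
    for f in range(n_families):
        x = fixture.centroids[f] + holdout_rng.normal(0.0, sigma, size=d)
        result = generate_set(
            x, params, n=n_generate, seed=seed, protein_id=f"holdout_{f}",
            vocab=vocab,
        )
        generated[f] = result.smiles_list
        n_valid = 0
        for s in result.smiles_list:
            mol = Chem.MolFromSmiles(s) if s else None
            if mol is not None:
                n_valid += 1
                canon = Chem.MolToSmiles(mol)
                g = family_of.get(canon)
                if g is not None:
                    fractions[f, g] += 1
        fractions[f] /= len(result.smiles_list)
        validity[f] = n_valid / len(result.smiles_list)
    return {
        "params": params,
        "config": config,
        "library": library,
        "fixture": fixture,
        "loss_history": history,
        "fractions": fractions,
        "validity": validity,
        "generated": generated,
    }
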