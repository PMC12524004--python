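"""SMILES curation pipeline and record-level filters.

Raw (protein, ligand) interaction records are filtered and normalized in
a fixed order: optional affinity/assay/organism record filters, removal
of stereochemistry, desalting (keep the organic fragment with the most
heavy atoms) and neutralization, rejection of carbon-free ("inorganic")
structures and of any structure containing an element outside the
whitelist {H, C, N, O, F, Br, I, Cl, P, S}, and emission of the
neutralized canonical SMILES.  A final dataset-level step trims unique
ligands whose SMILES character length falls in the extreme tails of the
length distribution.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "RawRecord",
    "CurationResult",
    "InteractionPair",
    "CuratedDataset",
    "curate_record",
    "curate_pairs",
    "trim_by_length",
    "ELEMENT_WHITELIST",
    "DEFAULT_MAX_AFFINITY_NM",
]

#: allowed chemical elements; anything else (metals included) is rejected
ELEMENT_WHITELIST = frozenset(
    {"H", "C", "N", "O", "F", "Br", "I", "Cl", "P", "S"}
)

#: default affinity cut-off (nanomolar); records above it are dropped
DEFAULT_MAX_AFFINITY_NM = 100.0

#: rejection stages, in pipeline order
REJECT_STAGES = (
    "affinity_filter",
    "parse_error",
    "desalt",
    "inorganic",
    "element_whitelist",
    "length_trim",
)

_UNCHARGER = rdMolStandardize.Uncharger()


@dataclass(frozen=True)
class RawRecord:
    """One raw interaction row before curation."""

    protein_id: str
    smiles: str
    affinity_nM: Optional[float] = None
    assay_type: Optional[str] = None
    organism: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be nonempty")


@dataclass(frozen=True)
class CurationResult:
    """Outcome of curating a single record."""

    accepted: bool
    canonical_smiles: Optional[str] = None
    reject_stage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.accepted != (self.canonical_smiles is not None):
            raise ValueError("accepted iff canonical_smiles present")
        if (not self.accepted) != (self.reject_stage is not None):
            raise ValueError("rejected iff reject_stage present")


@dataclass(frozen=True)
class InteractionPair:
    """A curated (protein, canonical ligand SMILES) training pair."""

    protein_id: str
    smiles: str
    affinity_nM: Optional[float] = None


@dataclass(frozen=True)
class CuratedDataset:
    """Deduplicated curated pairs plus a per-stage rejection report."""

    pairs: tuple[InteractionPair, ...]
    report: dict[str, int] = field(default_factory=dict)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p.protein_id for p in self.pairs)

    @property
    def ligands(self) -> frozenset[str]:
        return frozenset(p.smiles for p in self.pairs)


def _largest_organic_fragment(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Keep the fragment with the most heavy atoms (tie: larger MW)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        return None

    def key(frag: Chem.Mol) -> tuple[int, float]:
        from rdkit.Chem import Descriptors

        return (frag.GetNumHeavyAtoms(), Descriptors.MolWt(frag))

    return max(frags, key=key)


def _neutralize(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Remove formal charges by proton transfer where chemically valid."""
    neutral = _UNCHARGER.uncharge(mol)
    if neutral is None:
        return None
    if Chem.GetFormalCharge(neutral) != 0:
        return None
    try:
        Chem.SanitizeMol(neutral)
    except (Chem.rdchem.KekulizeException, Chem.rdchem.MolSanitizeException):
        return None
    return neutral


def curate_record(
    record: RawRecord,
    max_affinity_nM: float = DEFAULT_MAX_AFFINITY_NM,
    allowed_assay_types: Optional[frozenset[str]] = None,
    allowed_organisms: Optional[frozenset[str]] = None,
) -> CurationResult:
    """Apply the per-record curation pipeline.

    Stages, in order: record filters (affinity/assay/organism, applied
    only when the corresponding field is present), SMILES parsing,
    stereochemistry removal, desalting + neutralization, inorganic
    (carbon-free) rejection, element-whitelist check, canonical output.
    Unparseable SMILES are rejected with ``parse_error``, never raised.
    """
    if record.affinity_nM is not None and record.affinity_nM > max_affinity_nM:
        return CurationResult(False, reject_stage="affinity_filter")
    if (
        allowed_assay_types is not None
        and record.assay_type is not None
        and record.assay_type not in allowed_assay_types
    ):
        return CurationResult(False, reject_stage="affinity_filter")
    if (
        allowed_organisms is not None
        and record.organism is not None
        and record.organism not in allowed_organisms
    ):
        return CurationResult(False, reject_stage="affinity_filter")

    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        return CurationResult(False, reject_stage="parse_error")

    Chem.RemoveStereochemistry(mol)

    mol = _largest_organic_fragment(mol)
    if mol is None:
        return CurationResult(False, reject_stage="desalt")
    try:
        Chem.SanitizeMol(mol)
    except Chem.rdchem.MolSanitizeException:
        return CurationResult(False, reject_stage="desalt")
    mol = _neutralize(mol)
    if mol is None:
        return CurationResult(False, reject_stage="desalt")

    symbols = {atom.GetSymbol() for atom in mol.GetAtoms()}
    if "C" not in symbols:
        return CurationResult(False, reject_stage="inorganic")
    offending = symbols - ELEMENT_WHITELIST
    if offending:
        return CurationResult(False, reject_stage="element_whitelist")

    canonical = Chem.MolToSmiles(mol)
    return CurationResult(True, canonical_smiles=canonical)


def trim_by_length(
    dataset: CuratedDataset,
    lower_pct: float = 2.5,
    upper_pct: float = 2.5,
) -> CuratedDataset:
    """Drop unique ligands in the extreme tails of the length distribution.

    Percentiles are computed over the character lengths of the *unique*
    canonical ligand SMILES with linear interpolation; ligands strictly
    below the ``lower_pct`` percentile or strictly above the
    ``100 - upper_pct`` percentile are removed, together with every pair
    that references them.
    """
    if not dataset.pairs:
        raise ValueError("empty input")
    if lower_pct == 0 and upper_pct == 0:
        return dataset
    lengths = np.array(sorted(len(s) for s in dataset.ligands), dtype=float)
    lo = float(np.percentile(lengths, lower_pct, method="linear"))
    hi = float(np.percentile(lengths, 100.0 - upper_pct, method="linear"))
    keep = {s for s in dataset.ligands if lo <= len(s) <= hi}
    removed_pairs = sum(1 for p in dataset.pairs if p.smiles not in keep)
    report = dict(dataset.report)
    report["length_trim"] = report.get("length_trim", 0) + removed_pairs
    return CuratedDataset(
        pairs=tuple(p for p in dataset.pairs if p.smiles in keep),
        report=report,
    )


def curate_pairs(
    records: Iterable[RawRecord],
    max_affinity_nM: float = DEFAULT_MAX_AFFINITY_NM,
    trim: Optional[float] = 2.5,
    allowed_assay_types: Optional[frozenset[str]] = None,
    allowed_organisms: Optional[frozenset[str]] = None,
) -> CuratedDataset:
    """Curate records, deduplicate (protein, SMILES) pairs, optionally trim.

    The report reconciles: accepted + sum of per-stage rejections equals
    the number of input records ("duplicate" entries are counted within
    accepted; "length_trim" counts trimmed pairs separately).
    """
    counts: Counter[str] = Counter()
    seen: set[tuple[str, str]] = set()
    pairs: list[InteractionPair] = []
    total = 0
    for record in records:
        total += 1
        result = curate_record(
            record, max_affinity_nM, allowed_assay_types, allowed_organisms
        )
        if not result.accepted:
            counts[result.reject_stage] += 1
            continue
        counts["accepted"] += 1
        key = (record.protein_id, result.canonical_smiles)
        if key in seen:
            counts["duplicate"] += 1
            continue
        seen.add(key)
        pairs.append(
            InteractionPair(
                protein_id=record.protein_id,
                smiles=result.canonical_smiles,
                affinity_nM=record.affinity_nM,
            )
        )
    counts["input"] = total
    dataset = CuratedDataset(pairs=tuple(pairs), report=dict(counts))
    if not pairs:
        logger.warning("curation produced an empty dataset (%d records in)", total)
        return dataset
    if trim is not None and trim > 0:
        dataset = trim_by_length(dataset, lower_pct=trim, upper_pct=trim)
    return dataset
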