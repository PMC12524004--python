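"""Quality metrics for generated molecule sets.

Implements the standard de novo design evaluation profile: validity
(fraction of parseable SMILES), unicity (unique canonical forms among
the valid), novelty (unique forms absent from the training ligands),
internal diversity (mean pairwise Tanimoto distance over Morgan
fingerprints, radius 2 / 2048 bits), MaxSim (mean over generated
molecules of the maximum Tanimoto similarity to a reference active
set), QED drug-likeness, Ertl-Schuffenhauer synthetic accessibility,
Crippen logP, molecular weight, and the percentage of molecules free of
PAINS structural alerts.
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem, DataStructs, RDConfig, RDLogger
from rdkit.Chem import Descriptors, FilterCatalog, QED, rdFingerprintGenerator

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module)

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MetricsReport",
    "validity_unicity_novelty",
    "internal_diversity",
    "max_similarity",
    "property_profile",
    "per_protein_report",
]

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

_pains_params = FilterCatalog.FilterCatalogParams()
_pains_params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
_PAINS = FilterCatalog.FilterCatalog(_pains_params)


@dataclass(frozen=True)
class MetricsReport:
    """Per-protein generation quality profile.

    Percentages are on [0, 100]; diversity/similarity on [0, 1];
    undefined values (e.g. MaxSim with no reference set) are ``None``.
    """

    protein_id: str
    validity: float
    unicity: Optional[float]
    novelty: Optional[float]
    n_generated: int
    n_valid: int
    n_unique: int
    n_novel: int
    qed_mean: Optional[float] = None
    qed_sd: Optional[float] = None
    sa_mean: Optional[float] = None
    sa_sd: Optional[float] = None
    internal_div: Optional[float] = None
    max_sim: Optional[float] = None
    logp_mean: Optional[float] = None
    logp_sd: Optional[float] = None
    mw_mean: Optional[float] = None
    mw_sd: Optional[float] = None
    pains_free_pct: Optional[float] = None


def _canonical(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def validity_unicity_novelty(
    generated: Sequence[str], training_ligands: Iterable[str]
) -> tuple[float, Optional[float], Optional[float], list[str]]:
    """The validity -> unicity -> novelty funnel.

    validity: percent of generated strings that parse; unicity: percent
    of distinct canonical forms among the valid; novelty: percent of the
    unique forms absent from the (canonical) training ligands.  Returns
    the novel set — the "new molecules" — as the fourth element.
    """
    training = {c for s in training_ligands if (c := _canonical(s)) is not None}
    canon = [c for s in generated if (c := _canonical(s)) is not None]
    n_gen = len(generated)
    n_valid = len(canon)
    if n_gen == 0 or n_valid == 0:
        return 0.0, None, None, []
    unique = list(dict.fromkeys(canon))
    novel = [c for c in unique if c not in training]
    validity = 100.0 * n_valid / n_gen
    unicity = 100.0 * len(unique) / n_valid
    novelty = 100.0 * len(novel) / len(unique)
    return validity, unicity, novelty, novel


def _fingerprints(molecules: Sequence[str]):
    fps = []
    for s in molecules:
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            fps.append(_MORGAN.GetFingerprint(mol))
    return fps


def internal_diversity(molecules: Sequence[str]) -> Optional[float]:
    """Mean Tanimoto distance over all unordered distinct pairs."""
    fps = _fingerprints(molecules)
    if len(fps) < 2:
        return None
    total = 0.0
    count = 0
    for i in range(len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
        total += sum(1.0 - s for s in sims)
        count += len(sims)
    return total / count


def max_similarity(
    generated: Sequence[str], reference_actives: Sequence[str]
) -> Optional[float]:
    """Mean over generated molecules of the max Tanimoto similarity to
    any reference active."""
    gen_fps = _fingerprints(generated)
    ref_fps = _fingerprints(reference_actives)
    if not gen_fps or not ref_fps:
        return None
    best = [
        max(DataStructs.BulkTanimotoSimilarity(fp, ref_fps)) for fp in gen_fps
    ]
    return float(np.mean(best))


def property_profile(molecules: Sequence[str]) -> dict:
    """QED, SA, logP, molecular weight and PAINS profile of a molecule set.

    Returns per-molecule arrays plus mean/sd aggregates; molecules that
    fail a descriptor are logged and excluded from that descriptor.
    """
    qed_vals, sa_vals, logp_vals, mw_vals = [], [], [], []
    pains_free = 0
    n = 0
    for s in molecules:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            logger.warning("property_profile: unparseable SMILES %r skipped", s)
            continue
        n += 1
        try:
            qed_vals.append(QED.qed(mol))
        except Exception:  # pragma: no cover - rare rdkit descriptor failure
            logger.warning("QED failed for %r", s)
        try:
            sa_vals.append(sascorer.calculateScore(mol))
        except Exception:  # pragma: no cover
            logger.warning("SA failed for %r", s)
        logp_vals.append(Descriptors.MolLogP(mol))
        mw_vals.append(Descriptors.MolWt(mol))
        if not _PAINS.HasMatch(mol):
            pains_free += 1

    def agg(values: list[float]) -> tuple[Optional[float], Optional[float]]:
        if not values:
            return None, None
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    out: dict = {"n": n}
    out["qed"], out["qed_sd"] = agg(qed_vals)
    out["sa"], out["sa_sd"] = agg(sa_vals)
    out["logp"], out["logp_sd"] = agg(logp_vals)
    out["mw"], out["mw_sd"] = agg(mw_vals)
    out["pains_free_pct"] = 100.0 * pains_free / n if n else None
    out["per_molecule"] = {
        "qed": qed_vals,
        "sa": sa_vals,
        "logp": logp_vals,
        "mw": mw_vals,
    }
    return out


def per_protein_report(
    generated_by_protein: dict[str, Sequence[str]],
    training_ligands: Iterable[str],
    reference_actives_by_protein: Optional[dict[str, Sequence[str]]] = None,
) -> tuple[list[MetricsReport], dict]:
    """One MetricsReport per protein plus macro-averages across proteins."""
    training = list(training_ligands)
    rows: list[MetricsReport] = []
    for protein_id, generated in generated_by_protein.items():
        validity, unicity, novelty, novel = validity_unicity_novelty(
            generated, training
        )
        canon = [c for s in generated if (c := _canonical(s)) is not None]
        unique = list(dict.fromkeys(canon))
        profile = property_profile(novel) if novel else {}
        reference = (
            reference_actives_by_protein.get(protein_id)
            if reference_actives_by_protein
            else None
        )
        rows.append(
            MetricsReport(
                protein_id=protein_id,
                validity=validity,
                unicity=unicity,
                novelty=novelty,
                n_generated=len(generated),
                n_valid=len(canon),
                n_unique=len(unique),
                n_novel=len(novel),
                qed_mean=profile.get("qed"),
                qed_sd=profile.get("qed_sd"),
                sa_mean=profile.get("sa"),
                sa_sd=profile.get("sa_sd"),
                internal_div=internal_diversity(novel) if novel else None,
                max_sim=(
                    max_similarity(novel, reference)
                    if novel and reference
                    else None
                ),
                logp_mean=profile.get("logp"),
                logp_sd=profile.get("logp_sd"),
                mw_mean=profile.get("mw"),
                mw_sd=profile.get("mw_sd"),
                pains_free_pct=profile.get("pains_free_pct"),
            )
        )

    def macro(attr: str) -> Optional[float]:
        vals = [getattr(r, attr) for r in rows if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else None

    summary = {
        name: macro(name)
        for name in (
            "validity",
            "unicity",
            "novelty",
            "qed_mean",
            "sa_mean",
            "internal_div",
            "max_sim",
            "logp_mean",
            "mw_mean",
            "pains_free_pct",
        )
    }
    summary["n_proteins"] = len(rows)
    return rows, summary
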