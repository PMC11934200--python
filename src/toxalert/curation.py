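"""Per-task dataset curation with a full accounting audit.

For each assay task the curator removes, in a fixed, logged order:

1. records with no label for the task;
2. records whose SMILES does not parse (collected and reported);
3. multi-component records (salts/complexes) — dropped, not stripped;
4. duplicate structures: records are grouped by structural identity
   (Tanimoto = 1.0 on circular fingerprints, implemented as canonical-SMILES
   equality with an optional full pairwise fingerprint mode); a group whose
   labels disagree is dropped whole, otherwise only the first occurrence in
   input order is kept.

Every removal is counted so that
``initial - removals = final`` holds exactly, mirroring the accounting
columns of a curation summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .records import MoleculeRecord

logger = logging.getLogger(__name__)

#: Fingerprint used for the structural-identity test (wider than the model
#: fingerprint to reduce false identity collisions).
IDENTITY_RADIUS = 2
IDENTITY_NBITS = 2048


class SmilesParseError(ValueError):
    def __init__(self, mol_id: str, smiles: str):
        super().__init__(f"unparseable SMILES for {mol_id!r}: {smiles!r}")
        self.mol_id = mol_id
        self.smiles = smiles


def _identity_fp(mol: Chem.Mol):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=IDENTITY_RADIUS, fpSize=IDENTITY_NBITS)
    return gen.GetFingerprint(mol)


def canonical_identity(a: MoleculeRecord, b: MoleculeRecord) -> float:
    """Tanimoto coefficient |A∩B|/|A∪B| between two records' circular fingerprints.

    A coefficient of 1.0 is treated as structural identity for deduplication.
    """
    mols = []
    for rec in (a, b):
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise SmilesParseError(rec.mol_id, rec.smiles)
        mols.append(mol)
    return float(DataStructs.TanimotoSimilarity(_identity_fp(mols[0]), _identity_fp(mols[1])))


def is_multicomponent(smiles: str) -> bool:
    """True iff the molecule has more than one disconnected component."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError("<anonymous>", smiles)
    return len(Chem.GetMolFrags(mol)) > 1


@dataclass
class CurationAudit:
    """Removal accounting for one task; all counts are record counts."""

    task: str
    initial: int = 0
    no_data: int = 0
    parse_failures: int = 0
    unmatched_labels: int = 0
    duplicates: int = 0
    multiple_occurrences: int = 0
    salts_complexes: int = 0
    final: int = 0
    parse_failed_ids: list[str] = field(default_factory=list)

    def conserved(self) -> bool:
        removed = (self.no_data + self.parse_failures + self.salts_complexes
                   + self.unmatched_labels + self.duplicates + self.multiple_occurrences)
        return self.initial - removed == self.final

    def as_row(self) -> dict[str, object]:
        return {
            "Task": self.task,
            "# of initial compounds": self.initial,
            "Compounds with no data": self.no_data,
            "Compounds with unmatched data": self.unmatched_labels,
            "Duplicates": self.duplicates,
            "Multiple occurrences": self.multiple_occurrences,
            "Salts/Complexes": self.salts_complexes,
            "# of final compounds": self.final,
        }


def _identity_groups(records: Sequence[MoleculeRecord], mols: Sequence[Chem.Mol],
                     pairwise: bool) -> list[list[int]]:
    """Indices grouped by structural identity, preserving first-seen order.

    The default groups by canonical SMILES; ``pairwise`` instead compares all
    fingerprint pairs for Tanimoto = 1.0 (an O(n²) fidelity-audit mode that
    also merges distinct structures with colliding fingerprints).
    """
    if not pairwise:
        groups: dict[str, list[int]] = {}
        for i, mol in enumerate(mols):
            groups.setdefault(Chem.MolToSmiles(mol), []).append(i)
        return list(groups.values())
    fps = [_identity_fp(m) for m in mols]
    parent = list(range(len(records)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            if DataStructs.TanimotoSimilarity(fps[i], fps[j]) == 1.0:
                parent[find(j)] = find(i)
    grouped: dict[int, list[int]] = {}
    for i in range(len(fps)):
        grouped.setdefault(find(i), []).append(i)
    return [sorted(v) for v in grouped.values()]


def curate_task(records: Sequence[MoleculeRecord], task: str,
                pairwise_identity: bool = False) -> tuple[list[MoleculeRecord], CurationAudit]:
    """Curate one task's records; returns kept records and the audit.

    Removal order: missing labels → parse failures → multi-component →
    duplicate/conflict groups.  Within a duplicate group with consistent
    labels only the first occurrence in input order survives; a group with
    disagreeing labels is dropped entirely.
    """
    audit = CurationAudit(task=task, initial=len(records))

    labelled: list[MoleculeRecord] = []
    for r in records:
        if r.label(task) in (0, 1):
            labelled.append(r)
        else:
            audit.no_data += 1

    parsed: list[MoleculeRecord] = []
    mols: list[Chem.Mol] = []
    for r in labelled:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None:
            audit.parse_failures += 1
            audit.parse_failed_ids.append(r.mol_id)
            logger.warning("dropping unparseable SMILES %s (%s)", r.mol_id, task)
            continue
        parsed.append(r)
        mols.append(mol)

    single: list[MoleculeRecord] = []
    single_mols: list[Chem.Mol] = []
    for r, mol in zip(parsed, mols):
        if len(Chem.GetMolFrags(mol)) > 1:
            audit.salts_complexes += 1
        else:
            single.append(r)
            single_mols.append(mol)

    kept: list[Optional[MoleculeRecord]] = [None] * len(single)
    for group in _identity_groups(single, single_mols, pairwise_identity):
        group_labels = {single[i].label(task) for i in group}
        if len(group_labels) > 1:
            audit.unmatched_labels += len(group)
            continue
        kept[group[0]] = single[group[0]]
        removed = len(group) - 1
        if len(group) == 2:
            audit.duplicates += removed
        elif len(group) > 2:
            audit.multiple_occurrences += removed

    result = [r for r in kept if r is not None]
    audit.final = len(result)
    if not result:
        logger.warning("curation of task %s removed every record", task)
    assert audit.conserved(), "curation audit does not balance"
    return result, audit


def curate_all(records: Sequence[MoleculeRecord], tasks: Sequence[str],
               pairwise_identity: bool = False) -> dict[str, tuple[list[MoleculeRecord], CurationAudit]]:
    """Run `curate_task` for each task; curation is independent per task."""
    return {t: curate_task(records, t, pairwise_identity) for t in tasks}


def audits_to_frame(audits: Sequence[CurationAudit]):
    """Audit rows as a DataFrame shaped like a curation summary table."""
    import pandas as pd

    return pd.DataFrame([a.as_row() for a in audits])
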