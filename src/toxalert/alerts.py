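"""From local explanations to ranked toxic-alert tables.

A molecule's explanation weights live on fingerprint bits; each bit active
in the molecule is mapped back to its environment fragment(s), giving
per-fragment signed attributions.  Molecules are classified by the
signed-weight rule (disruptor iff the positive weight sum exceeds the
negative sum).  Attributions from confidently and correctly predicted
actives are filtered by a weight floor and aggregated by canonical fragment
SMILES into alert entries ranked by total contributed weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .explain import LocalExplanation
from .featurize import BitFingerprint, fragments_for_bit

#: Model-probability threshold for "confidently predicted disruptor".
DEFAULT_CONFIDENCE = 0.8
#: Attribution weights at or below this floor are considered insignificant.
DEFAULT_WEIGHT_FLOOR = 0.1


@dataclass
class FragmentAttribution:
    mol_id: str
    bit: int
    fragment_smiles: str
    atom_indices: list[int]
    weight: float


@dataclass
class MoleculeVerdict:
    mol_id: str
    positive_sum: float
    negative_sum: float

    @property
    def is_disruptor(self) -> bool:
        return self.positive_sum > self.negative_sum


@dataclass
class AlertEntry:
    fragment_smiles: str
    occurrences: int
    total_weight: float


def select_confident_actives(explanations: Sequence[LocalExplanation],
                             y_true: Sequence[int],
                             confidence: float = DEFAULT_CONFIDENCE,
                             prediction_threshold: float = 0.5
                             ) -> list[LocalExplanation]:
    """Keep explanations of true actives predicted active with high confidence.

    A molecule passes iff its true label is 1, the model's class-1
    probability predicts label 1, and that probability is at least
    ``confidence``.
    """
    if len(explanations) != len(y_true):
        raise ValueError("explanations and labels must align")
    kept = []
    for exp, label in zip(explanations, y_true):
        predicted = exp.model_probability >= prediction_threshold
        if label == 1 and predicted and exp.model_probability >= confidence:
            kept.append(exp)
    return kept


def attribute_fragments(explanation: LocalExplanation, fp: BitFingerprint,
                        mol: Chem.Mol | None = None) -> list[FragmentAttribution]:
    """Map a molecule's weighted bits to its substructure fragments.

    Bits carrying weight but inactive in this molecule contribute nothing;
    a colliding bit yields one attribution per environment, all sharing the
    bit's weight.
    """
    if mol is None:
        mol = Chem.MolFromSmiles(fp.smiles)
    out: list[FragmentAttribution] = []
    for bit, weight in explanation.weights:
        if not fp.bits[bit]:
            continue
        for frag in fragments_for_bit(mol, bit, fp=fp):
            out.append(FragmentAttribution(mol_id=explanation.mol_id, bit=bit,
                                           fragment_smiles=frag.smiles,
                                           atom_indices=list(frag.atom_indices),
                                           weight=weight))
    return out


def verdict(attributions: Sequence[FragmentAttribution], mol_id: str = "") -> MoleculeVerdict:
    """Signed-weight rule: disruptor iff Σ positive weights > Σ negative weights."""
    if attributions and not mol_id:
        mol_id = attributions[0].mol_id
    pos = sum(a.weight for a in attributions if a.weight > 0)
    neg = sum(-a.weight for a in attributions if a.weight < 0)
    return MoleculeVerdict(mol_id=mol_id, positive_sum=pos, negative_sum=neg)


def aggregate_alerts(attributions: Iterable[FragmentAttribution],
                     weight_floor: float = DEFAULT_WEIGHT_FLOOR,
                     count_rows: bool = False,
                     floor_on_totals: bool = False) -> list[AlertEntry]:
    """Rank fragments by their total contribution across molecules.

    Attributions with weight ≤ ``weight_floor`` are dropped (per-attribution
    by default; ``floor_on_totals`` instead filters aggregated totals).
    Occurrences count distinct (molecule, fragment) pairs unless
    ``count_rows`` — the raw-attribution alternative — is requested.
    Entries are sorted by total weight descending, ties broken by
    occurrences then fragment SMILES.
    """
    attributions = list(attributions)
    if not floor_on_totals:
        attributions = [a for a in attributions if a.weight > weight_floor]
    pairs: dict[str, set[tuple[str, str]]] = {}
    totals: dict[str, float] = {}
    rows: dict[str, int] = {}
    for a in attributions:
        totals[a.fragment_smiles] = totals.get(a.fragment_smiles, 0.0) + a.weight
        rows[a.fragment_smiles] = rows.get(a.fragment_smiles, 0) + 1
        pairs.setdefault(a.fragment_smiles, set()).add((a.mol_id, a.fragment_smiles))
    entries = [
        AlertEntry(fragment_smiles=f,
                   occurrences=(rows[f] if count_rows else len(pairs[f])),
                   total_weight=totals[f])
        for f in totals
    ]
    if floor_on_totals:
        entries = [e for e in entries if e.total_weight > weight_floor]
    else:
        entries = [e for e in entries if e.total_weight > 0]
    entries.sort(key=lambda e: (-e.total_weight, -e.occurrences, e.fragment_smiles))
    return entries


def render_highlights(mol: Chem.Mol, attributions: Sequence[FragmentAttribution]) -> dict:
    """Serializable atom/bond highlight sets per fragment (no drawing here)."""
    per_fragment = []
    union_atoms: set[int] = set()
    union_bonds: set[int] = set()
    for a in attributions:
        atoms = sorted(a.atom_indices)
        bonds = []
        atom_set = set(atoms)
        for bond in mol.GetBonds():
            if bond.GetBeginAtomIdx() in atom_set and bond.GetEndAtomIdx() in atom_set:
                bonds.append(bond.GetIdx())
        per_fragment.append({"fragment_smiles": a.fragment_smiles, "bit": a.bit,
                             "weight": a.weight, "atoms": atoms, "bonds": sorted(bonds)})
        union_atoms.update(atoms)
        union_bonds.update(bonds)
    return {"fragments": per_fragment,
            "union_atoms": sorted(union_atoms), "union_bonds": sorted(union_bonds)}


def alerts_to_csv(entries: Sequence[AlertEntry], path: str | Path) -> None:
    pd.DataFrame([{"fragment_smiles": e.fragment_smiles,
                   "occurrences": e.occurrences,
                   "total_weight": e.total_weight} for e in entries]).to_csv(path, index=False)


def highlights_to_json(highlights: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(highlights, indent=1))
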