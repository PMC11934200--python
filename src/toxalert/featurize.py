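"""1024-bit circular fingerprints with bit→atom-environment bookkeeping.

Extended-connectivity fingerprints hash each atom's neighbourhood, at radii
0..R, into bits of a fixed-width binary vector.  Folding to 1024 bits can
merge several distinct (center atom, radius) environments into one bit — a
*bit collision*.  Attribution of model explanations back to substructures
requires the inverse map, so each fingerprint here carries the full
environment list per active bit, and `fragments_for_bit` reconstructs the
actual subgraph (atoms, bonds, canonical fragment SMILES) behind any bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

DEFAULT_RADIUS = 2  # ECFP4-equivalent
DEFAULT_NBITS = 1024


class SmilesError(ValueError):
    pass


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


@dataclass
class BitFingerprint:
    """Folded binary fingerprint plus the environments behind each active bit.

    ``environments`` maps an active bit index to the list of
    ``(center_atom_index, radius)`` pairs that set it; a bit with more than
    one entry is a collision and is attributed to every environment.
    """

    bits: np.ndarray
    environments: dict[int, list[tuple[int, int]]]
    smiles: str = ""
    n_bits: int = DEFAULT_NBITS
    radius: int = DEFAULT_RADIUS

    def on_bits(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.bits)]


def fingerprint(smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_NBITS) -> BitFingerprint:
    """ECFP of the given radius folded to ``n_bits``, with environment map."""
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    fp = gen.GetFingerprint(mol, additionalOutput=ao)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    envs = {int(b): [(int(a), int(r)) for a, r in pairs]
            for b, pairs in ao.GetBitInfoMap().items()}
    return BitFingerprint(bits=bits, environments=envs, smiles=smiles,
                          n_bits=n_bits, radius=radius)


@dataclass
class FeatureMatrix:
    """Dense n×n_bits binary matrix with row identifiers aligned to rows."""

    rows: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        if self.rows.shape[0] != len(self.row_ids):
            raise ValueError("row count must equal id count")

    @property
    def n_bits(self) -> int:
        return self.rows.shape[1]

    def bit_frequencies(self) -> np.ndarray:
        """Per-bit Bernoulli frequencies over the rows (the perturbation prior)."""
        return self.rows.mean(axis=0)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.rows, index=self.row_ids,
                          columns=[f"bit_{i}" for i in range(self.n_bits)])
        df.to_csv(path, index_label="mol_id")

    def to_sparse_text(self, path: str | Path) -> None:
        """Coordinate text format: one `mol_id<TAB>bit` line per set bit."""
        with open(path, "w") as fh:
            fh.write(f"# {self.rows.shape[0]} x {self.n_bits} binary, coordinate list\n")
            for rid, row in zip(self.row_ids, self.rows):
                for b in np.flatnonzero(row):
                    fh.write(f"{rid}\t{int(b)}\n")


def feature_matrix(records: Iterable, radius: int = DEFAULT_RADIUS,
                   n_bits: int = DEFAULT_NBITS) -> FeatureMatrix:
    """Fingerprint a sequence of MoleculeRecords into a FeatureMatrix."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in records:
        fp = fingerprint(rec.smiles, radius=radius, n_bits=n_bits)
        ids.append(rec.mol_id)
        rows.append(fp.bits)
    return FeatureMatrix(rows=np.array(rows, dtype=np.uint8), row_ids=ids)


@dataclass
class FragmentDescriptor:
    """One environment subgraph behind a fingerprint bit."""

    atom_indices: list[int]
    bond_indices: list[int]
    smiles: str
    center: int = -1
    radius: int = 0


def _environment_fragment(mol: Chem.Mol, center: int, radius: int) -> FragmentDescriptor:
    if radius == 0:
        smi = Chem.MolFragmentToSmiles(mol, atomsToUse=[center], canonical=True)
        return FragmentDescriptor([center], [], smi, center, 0)
    bond_ids = list(Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center))
    atoms = {center}
    for b in bond_ids:
        bond = mol.GetBondWithIdx(b)
        atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    smi = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms), bondsToUse=bond_ids,
                                   canonical=True)
    return FragmentDescriptor(sorted(atoms), sorted(bond_ids), smi, center, radius)


def fragments_for_bit(mol_or_smiles: Chem.Mol | str, bit: int,
                      fp: BitFingerprint | None = None,
                      radius: int = DEFAULT_RADIUS,
                      n_bits: int = DEFAULT_NBITS) -> list[FragmentDescriptor]:
    """All fragment subgraphs whose hashed environment set ``bit``.

    An inactive bit yields an empty list.  A colliding bit yields one
    descriptor per environment.
    """
    if isinstance(mol_or_smiles, str):
        smiles = mol_or_smiles
        mol = _mol_from_smiles(smiles)
    else:
        mol = mol_or_smiles
        smiles = Chem.MolToSmiles(mol)
    if fp is None:
        fp = fingerprint(smiles, radius=radius, n_bits=n_bits)
    return [_environment_fragment(mol, center, r)
            for center, r in fp.environments.get(int(bit), [])]


def fragment_query(fragment_smiles: str) -> Chem.Mol:
    """Parse an environment-fragment SMILES into a substructure query.

    Fragment SMILES keep the parent's aromaticity flags, so they are parsed
    without sanitisation (a lone aromatic path such as ``ccc`` is not a
    valid molecule on its own) and matched as written.
    """
    q = Chem.MolFromSmiles(fragment_smiles, sanitize=False)
    if q is None:
        raise SmilesError(f"unparseable fragment SMILES: {fragment_smiles!r}")
    q.UpdatePropertyCache(strict=False)
    return q
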