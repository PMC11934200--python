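"""Molecule records and the CSV dialect shared by every pipeline stage.

A dataset is a flat CSV with columns ``mol_id``, ``smiles`` and one column
per assay task (``NR-AR``-style headers are accepted and normalised).  Label
cells hold 0, 1 or blank (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: The five nuclear-receptor tasks: androgen receptor, estrogen receptor,
#: aryl-hydrocarbon receptor, aromatase and PPAR-gamma.
DEFAULT_TASKS: tuple[str, ...] = ("AR", "ER", "AhR", "ARO", "PPAR")

#: Column-header aliases for the MoleculeNet-style raw table.
_TASK_ALIASES: dict[str, str] = {
    "NR-AR": "AR",
    "NR-ER": "ER",
    "NR-AhR": "AhR",
    "NR-Aromatase": "ARO",
    "NR-PPAR-gamma": "PPAR",
}


@dataclass
class MoleculeRecord:
    """One SMILES with per-task binary/missing activity labels.

    ``labels`` maps a task name to 0 (inactive), 1 (active) or ``None``
    (missing assay data).
    """

    mol_id: str
    smiles: str
    labels: dict[str, Optional[int]] = field(default_factory=dict)

    def label(self, task: str) -> Optional[int]:
        return self.labels.get(task)


def _normalise_task(name: str) -> str:
    return _TASK_ALIASES.get(name, name)


def read_dataset_csv(path: str | Path, tasks: Sequence[str] | None = None) -> list[MoleculeRecord]:
    """Read a labelled SMILES table.

    Parameters
    ----------
    path:
        CSV with columns ``mol_id``, ``smiles`` and one or more task columns.
    tasks:
        Restrict to these task names (after alias normalisation).  By default
        every non-id, non-smiles column is kept.
    """
    df = pd.read_csv(path, dtype={"mol_id": str, "smiles": str})
    if "mol_id" not in df.columns or "smiles" not in df.columns:
        raise ValueError(f"{path}: expected columns 'mol_id' and 'smiles'")
    label_cols = [c for c in df.columns if c not in ("mol_id", "smiles")]
    records: list[MoleculeRecord] = []
    for row in df.itertuples(index=False):
        row_d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        labels: dict[str, Optional[int]] = {}
        for col in label_cols:
            task = _normalise_task(col)
            if tasks is not None and task not in tasks:
                continue
            val = getattr(row, col, row_d.get(col))
            labels[task] = None if pd.isna(val) else int(val)
        records.append(MoleculeRecord(mol_id=str(row_d["mol_id"]), smiles=str(row_d["smiles"]), labels=labels))
    return records


def write_dataset_csv(records: Iterable[MoleculeRecord], path: str | Path,
                      tasks: Sequence[str] | None = None) -> None:
    """Write records back to the shared CSV dialect (blank = missing)."""
    records = list(records)
    if tasks is None:
        seen: dict[str, None] = {}
        for r in records:
            for t in r.labels:
                seen.setdefault(t)
        tasks = list(seen)
    rows = []
    for r in records:
        row: dict[str, object] = {"mol_id": r.mol_id, "smiles": r.smiles}
        for t in tasks:
            v = r.labels.get(t)
            row[t] = "" if v is None else int(v)
        rows.append(row)
    pd.DataFrame(rows, columns=["mol_id", "smiles", *tasks]).to_csv(path, index=False)


def labels_vector(records: Sequence[MoleculeRecord], task: str) -> list[Optional[int]]:
    """Per-record labels for one task, aligned with ``records``."""
    return [r.label(task) for r in records]
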