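"""Synthetic SMILES benchmark with planted toxic-alert substructures.

The generator decorates simple carbon/oxygen carrier scaffolds with one of a
small set of alert fragments (thiophosphate, sulfamate ester, anilide,
carbamate, sulfamide, thiocyanate by default).  A molecule is truly active
iff it carries an alert fragment; observed labels can then be flipped with a
configurable noise rate.  Because the carriers contain no N, S or P atoms,
an alert can never arise by accident, so ground truth is exact and every
downstream stage (curation, modelling, explanation, alert mining) can be
validated against it.

This emulates the *statistical* structure assumed by the analysis — binary
labels caused by substructures, class imbalance, label noise — not realistic
chemistry-space sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import RWMol

from .records import MoleculeRecord, write_dataset_csv


class GenerationError(RuntimeError):
    """Raised when a molecule cannot be assembled from the requested parts."""


@dataclass(frozen=True)
class AlertFragment:
    """An activity-conferring substructure.

    ``fragment`` is a SMILES whose atom 0 is the attachment point; ``smarts``
    is the substructure query used both for ground-truth matching and for
    recovery checks.
    """

    name: str
    fragment: str
    smarts: str

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ValueError(f"invalid SMARTS for alert {self.name!r}: {self.smarts}")
        return q


#: Default planted alerts, mirroring the substructure families the analysis
#: is designed to rediscover.
DEFAULT_ALERTS: tuple[AlertFragment, ...] = (
    AlertFragment("thiophosphate", "OP(=S)(OC)OC", "OP(=S)(OC)OC"),
    AlertFragment("sulfamate_ester", "OS(=O)(=O)N", "OS(=O)(=O)N"),
    AlertFragment("anilide", "C(=O)Nc1ccccc1", "C(=O)Nc1ccccc1"),
    AlertFragment("carbamate", "OC(=O)NC", "OC(=O)NC"),
    AlertFragment("sulfamide", "NS(=O)(=O)N", "NS(=O)(=O)N"),
    AlertFragment("thiocyanate", "SC#N", "SC#N"),
)

#: Innocuous decorations used to diversify molecules without creating alerts
#: (carbon/oxygen/halogen only — no alert contains solely these atoms).
BENIGN_FRAGMENTS: tuple[str, ...] = ("C", "CC", "CCC", "O", "OC", "OCC", "C(C)C", "Cl", "F")


def default_scaffolds() -> list[str]:
    """Carrier SMILES shipped with the package (C/O-only drug-like cores)."""
    text = resources.files("toxalert.data").joinpath("scaffolds.smi").read_text()
    return [line.split()[0] for line in text.splitlines() if line.strip()]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``imbalance_ratio``, when set, overrides ``n_inactive`` with
    ``round(n_active * imbalance_ratio)`` (inactive:active).
    """

    n_active: int = 250
    n_inactive: int = 250
    label_noise: float = 0.0
    imbalance_ratio: Optional[float] = None
    alert_patterns: Sequence[AlertFragment] = DEFAULT_ALERTS
    scaffold_pool: Sequence[str] = field(default_factory=default_scaffolds)
    task: str = "AR"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 0 or self.n_inactive < 0:
            raise ValueError("n_active and n_inactive must be non-negative")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")
        if not self.scaffold_pool:
            raise ValueError("scaffold_pool must be non-empty")
        for a in self.alert_patterns:
            a.query()  # raises on invalid SMARTS

    @property
    def effective_n_inactive(self) -> int:
        if self.imbalance_ratio is None:
            return self.n_inactive
        return int(round(self.n_active * self.imbalance_ratio))


@dataclass
class TruthEntry:
    """Pre-noise ground truth for one record."""

    mol_id: str
    has_alert: bool
    pattern_id: Optional[str]
    label_flipped: bool


@dataclass
class SyntheticDataset:
    records: list[MoleculeRecord]
    truth: dict[str, TruthEntry]
    task: str
    spec: Optional[SyntheticSpec] = None

    def labels(self) -> list[int]:
        return [int(r.labels[self.task]) for r in self.records]

    def write(self, csv_path: str | Path, truth_path: str | Path | None = None) -> None:
        write_dataset_csv(self.records, csv_path, tasks=[self.task])
        if truth_path is not None:
            payload = {
                mid: {"has_alert": t.has_alert, "pattern_id": t.pattern_id,
                      "label_flipped": t.label_flipped}
                for mid, t in self.truth.items()
            }
            Path(truth_path).write_text(json.dumps(payload, indent=1))


def _eligible_sites(mol: Chem.Mol) -> list[int]:
    """Ring or terminal carbons with a spare hydrogen to attach at."""
    sites = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetTotalNumHs() < 1:
            continue
        if atom.IsInRing() or atom.GetDegree() <= 1:
            sites.append(atom.GetIdx())
    return sites


def attach_fragment(scaffold_smiles: str, fragment_smiles: str, site: int) -> str:
    """Bond atom 0 of ``fragment_smiles`` to ``site`` of the scaffold.

    Returns the canonical SMILES of the decorated, sanitised molecule.
    """
    scaffold = Chem.MolFromSmiles(scaffold_smiles)
    frag = Chem.MolFromSmiles(fragment_smiles)
    if scaffold is None or frag is None:
        raise GenerationError(f"unparseable part: {scaffold_smiles!r} + {fragment_smiles!r}")
    combo = RWMol(Chem.CombineMols(scaffold, frag))
    combo.AddBond(site, scaffold.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - valence errors are config bugs
        raise GenerationError(
            f"cannot attach {fragment_smiles!r} at atom {site} of {scaffold_smiles!r}: {exc}"
        ) from exc
    return Chem.MolToSmiles(mol)


def _build_molecule(rng: np.random.Generator, scaffolds: Sequence[str],
                    alert: Optional[AlertFragment], n_benign: int) -> str:
    smiles = scaffolds[int(rng.integers(len(scaffolds)))]
    fragments = [BENIGN_FRAGMENTS[int(rng.integers(len(BENIGN_FRAGMENTS)))] for _ in range(n_benign)]
    if alert is not None:
        fragments.insert(int(rng.integers(len(fragments) + 1)), alert.fragment)
    for frag in fragments:
        mol = Chem.MolFromSmiles(smiles)
        sites = _eligible_sites(mol)
        if not sites:
            raise GenerationError(f"no attachment site left on {smiles!r}"
                                  + (f" for alert {alert.name!r}" if alert else ""))
        smiles = attach_fragment(smiles, frag, sites[int(rng.integers(len(sites)))])
    return smiles


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a seeded, deterministic dataset of unique single-component SMILES.

    Actives carry exactly one sampled alert fragment plus optional benign
    decorations; inactives carry benign decorations only.  Labels are flipped
    independently with probability ``spec.label_noise`` after construction;
    ``truth`` records the pre-noise state.
    """
    rng = np.random.default_rng(spec.seed)
    alerts = list(spec.alert_patterns)
    queries = [a.query() for a in alerts]
    n_inactive = spec.effective_n_inactive

    seen: set[str] = set()
    entries: list[tuple[str, bool, Optional[str]]] = []  # (smiles, truly_active, pattern)

    def sample(active: bool, want: int) -> None:
        tries = 0
        made = 0
        while made < want:
            tries += 1
            if tries > 200 * max(want, 1):
                raise GenerationError(
                    f"could not generate {want} unique {'active' if active else 'inactive'} molecules"
                )
            alert = alerts[int(rng.integers(len(alerts)))] if active else None
            n_benign = int(rng.integers(0, 3))
            try:
                smiles = _build_molecule(rng, spec.scaffold_pool, alert, n_benign)
            except GenerationError:
                continue
            if smiles in seen or "." in smiles:
                continue
            mol = Chem.MolFromSmiles(smiles)
            matched = any(mol.HasSubstructMatch(q) for q in queries)
            if matched != active:
                continue  # benign decoration stack can never form an alert, but stay safe
            seen.add(smiles)
            entries.append((smiles, active, alert.name if alert else None))
            made += 1

    sample(True, spec.n_active)
    sample(False, n_inactive)

    order = rng.permutation(len(entries))
    flips = rng.random(len(entries)) < spec.label_noise
    records: list[MoleculeRecord] = []
    truth: dict[str, TruthEntry] = {}
    for pos, idx in enumerate(order):
        smiles, active, pattern = entries[idx]
        flipped = bool(flips[pos])
        label = int(active) ^ int(flipped)
        mol_id = f"SYN-{pos:05d}"
        records.append(MoleculeRecord(mol_id, smiles, {spec.task: label}))
        truth[mol_id] = TruthEntry(mol_id, active, pattern, flipped)
    return SyntheticDataset(records=records, truth=truth, task=spec.task, spec=spec)


#: Representative carriers used as attachment context when deciding whether a
#: mined fragment recovers a planted alert.
_RECOVERY_CONTEXTS: tuple[str, ...] = ("c1ccccc1", "C1CCCCC1", "CC")


def fragment_recovers_alert(fragment_smiles: str, alert: AlertFragment) -> bool:
    """Does a mined environment fragment point at the planted alert?

    Circular-fingerprint environments centred on the alert's boundary atoms
    legitimately include the attachment-point scaffold atom, so a literal
    subgraph test against the bare fragment would reject honest recoveries.
    Instead the fragment is matched inside the alert capped onto
    representative carriers (benzene, cyclohexane, methyl); it recovers the
    alert iff it matches at least one context molecule with at least one
    matched atom inside the planted substructure.
    """
    from .featurize import fragment_query  # local import avoids a cycle

    try:
        query = fragment_query(fragment_smiles)
    except Exception:
        return False
    alert_q = alert.query()
    for carrier in _RECOVERY_CONTEXTS:
        mol = Chem.MolFromSmiles(carrier)
        site = _eligible_sites(mol)[0]
        try:
            context = Chem.MolFromSmiles(attach_fragment(carrier, alert.fragment, site))
        except GenerationError:
            continue
        alert_atoms = set()
        for match in context.GetSubstructMatches(alert_q):
            alert_atoms.update(match)
        for match in context.GetSubstructMatches(query):
            if alert_atoms & set(match):
                return True
    return False


@dataclass
class InjectionAudit:
    """What `inject_duplicates` planted, as expected curation removal counts."""

    n_dup: int
    n_conflict: int
    n_salt: int

    @property
    def expected_removals(self) -> dict[str, int]:
        # each conflict pair (original + flipped copy) is dropped whole
        return {
            "duplicates": self.n_dup,
            "unmatched": 2 * self.n_conflict,
            "salts_complexes": self.n_salt,
        }


COUNTER_IONS: tuple[str, ...] = ("[Na+]", "[Cl-]", "[K+]")


def inject_duplicates(ds: SyntheticDataset, n_dup: int = 0, n_conflict: int = 0,
                      n_salt: int = 0, seed: int = 0) -> tuple[SyntheticDataset, InjectionAudit]:
    """Plant curation defects: exact duplicates, label conflicts, salt forms.

    Appends ``n_dup`` exact-duplicate records and ``n_conflict`` duplicates
    with flipped labels, and rewrites ``n_salt`` existing records as
    multi-component SMILES (original plus a counter-ion).  Source records are
    chosen disjointly so each defect maps to exactly one curation removal.
    """
    n = len(ds.records)
    if n_dup + n_conflict + n_salt > n:
        raise ValueError("cannot inject more defects than records")
    rng = np.random.default_rng(seed)
    picks = rng.choice(n, size=n_dup + n_conflict + n_salt, replace=False)
    dup_idx = picks[:n_dup]
    con_idx = picks[n_dup:n_dup + n_conflict]
    salt_idx = picks[n_dup + n_conflict:]

    records = [MoleculeRecord(r.mol_id, r.smiles, dict(r.labels)) for r in ds.records]
    truth = dict(ds.truth)
    for j, i in enumerate(dup_idx):
        src = records[i]
        records.append(MoleculeRecord(f"DUP-{j:04d}", src.smiles, dict(src.labels)))
    for j, i in enumerate(con_idx):
        src = records[i]
        flipped = {t: (None if v is None else 1 - v) for t, v in src.labels.items()}
        records.append(MoleculeRecord(f"CON-{j:04d}", src.smiles, flipped))
    for i in salt_idx:
        ion = COUNTER_IONS[int(rng.integers(len(COUNTER_IONS)))]
        records[i] = MoleculeRecord(records[i].mol_id, records[i].smiles + "." + ion,
                                    dict(records[i].labels))
    out = SyntheticDataset(records=records, truth=truth, task=ds.task, spec=ds.spec)
    return out, InjectionAudit(n_dup=n_dup, n_conflict=n_conflict, n_salt=n_salt)
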