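"""Library parsing, curation, and 3D conformer generation.

A molecule library is a CSV/TSV table with columns ``id``, ``smiles`` and
``activity_score`` (PubChem-style 0-100 score, may be missing).  Curation
mirrors standard screening-library hygiene: salt stripping (keep the largest
organic fragment), removal of carbon-free "inorganic" entries, and
deduplication on canonical SMILES (stereochemistry retained, so distinct
stereoisomers stay distinct records).

Conformers are produced by distance-geometry embedding (ETKDG) followed by
MMFF94 minimisation, yielding a single low-energy conformer per molecule with
explicit hydrogens.  The same seed always reproduces the same coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import EmbeddingError, LibraryFormatError, SDFParseError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "smiles", "activity_score")

#: retry budget for distance-geometry embedding before giving up
EMBED_RETRIES = 5


@dataclass
class MoleculeRecord:
    """One chemical: identifier, structure, assay score, binary label."""

    id: str
    smiles: str
    activity_score: float | None = None
    label: str | None = None  # "active" | "inactive" | None


@dataclass
class Conformer3D:
    """MMFF-minimised 3D structure: atoms with coordinates, bonds, energy."""

    mol_id: str
    atoms: list[tuple[str, float, float, float]]  # (element, x, y, z) in Angstrom
    bonds: list[tuple[int, int, int]]  # (atom_i, atom_j, integer order)
    energy: float = 0.0

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class CurationRules:
    drop_duplicates: bool = True
    drop_inorganic: bool = True
    strip_salts: bool = True


def parse_library(path: str | Path) -> list[MoleculeRecord]:
    """Read a CSV or TSV molecule table into records, preserving row order.

    Missing activity scores are kept as ``None``.  Raises
    :class:`LibraryFormatError` if a required column is absent or a score
    cannot be interpreted as a number.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryFormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    records: list[MoleculeRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        raw_score = getattr(row, "activity_score").strip()
        if raw_score == "":
            score = None
        else:
            try:
                score = float(raw_score)
            except ValueError as exc:
                raise LibraryFormatError(
                    f"{path.name} row {idx}: unreadable activity_score {raw_score!r}"
                ) from exc
        records.append(
            MoleculeRecord(id=getattr(row, "id"), smiles=getattr(row, "smiles"),
                           activity_score=score)
        )
    return records


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment, preferring fragments that contain carbon."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol

    def key(frag: Chem.Mol) -> tuple[int, int, int]:
        has_c = any(a.GetSymbol() == "C" for a in frag.GetAtoms())
        return (int(has_c), frag.GetNumHeavyAtoms(), frag.GetNumAtoms())

    return max(frags, key=key)


def _is_organic(mol: Chem.Mol) -> bool:
    return any(a.GetSymbol() == "C" for a in mol.GetAtoms())


def curate(records: Sequence[MoleculeRecord],
           rules: CurationRules | None = None) -> list[MoleculeRecord]:
    """Apply salt stripping, inorganic removal, and deduplication.

    Unparseable SMILES are dropped (counted in the log, never raised).  The
    operation is idempotent: a curated library passes through unchanged.
    """
    rules = rules or CurationRules()
    out: list[MoleculeRecord] = []
    seen: set[str] = set()
    n_unparseable = 0
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            n_unparseable += 1
            continue
        if rules.strip_salts:
            mol = _largest_organic_fragment(mol)
        if rules.drop_inorganic and not _is_organic(mol):
            continue
        canonical = Chem.MolToSmiles(mol)
        if rules.drop_duplicates:
            if canonical in seen:
                continue
            seen.add(canonical)
        out.append(replace(rec, smiles=canonical))
    if n_unparseable:
        logger.warning("curate: dropped %d unparseable SMILES", n_unparseable)
    return out


def _mol_to_conformer(mol: Chem.Mol, mol_id: str, energy: float) -> Conformer3D:
    conf = mol.GetConformer()
    atoms = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        atoms.append((atom.GetSymbol(), pos.x, pos.y, pos.z))
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), max(1, int(b.GetBondTypeAsDouble())))
        for b in mol.GetBonds()
    ]
    return Conformer3D(mol_id=mol_id, atoms=atoms, bonds=bonds, energy=energy)


def embed_3d(record: MoleculeRecord, seed: int = 0) -> Conformer3D:
    """Generate one MMFF94-minimised conformer with explicit hydrogens.

    Deterministic: the same record and seed give bitwise-identical
    coordinates.  Embedding is retried up to :data:`EMBED_RETRIES` times with
    incremented seeds before an :class:`EmbeddingError` is raised.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise EmbeddingError(record.id, f"invalid SMILES {record.smiles!r}")
    mol = Chem.AddHs(mol)
    for attempt in range(EMBED_RETRIES):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + attempt
        if AllChem.EmbedMolecule(mol, params) == 0:
            break
    else:
        raise EmbeddingError(record.id, f"embedding failed after {EMBED_RETRIES} tries")
    energy = float("nan")
    if AllChem.MMFFHasAllMoleculeParams(mol):
        AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
        props = AllChem.MMFFGetMoleculeProperties(mol)
        ff = AllChem.MMFFGetMoleculeForceField(mol, props)
        energy = float(ff.CalcEnergy())
    return _mol_to_conformer(mol, record.id, energy)


def mmff_energy(conf: Conformer3D) -> float:
    """MMFF94 single-point energy of a conformer (used as an oracle check)."""
    mol = _conformer_to_mol(conf)
    Chem.SanitizeMol(mol)
    props = AllChem.MMFFGetMoleculeProperties(mol)
    ff = AllChem.MMFFGetMoleculeForceField(mol, props)
    return float(ff.CalcEnergy())


def _conformer_to_mol(conf: Conformer3D) -> Chem.RWMol:
    mol = Chem.RWMol()
    for element, *_ in conf.atoms:
        mol.AddAtom(Chem.Atom(element))
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE}
    for i, j, order in conf.bonds:
        mol.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
    c = Chem.Conformer(len(conf.atoms))
    for idx, (_, x, y, z) in enumerate(conf.atoms):
        c.SetAtomPosition(idx, (x, y, z))
    mol.AddConformer(c)
    for atom in mol.GetAtoms():
        atom.SetNoImplicit(True)
    return mol


def write_sdf(conformers: Sequence[Conformer3D], path: str | Path) -> None:
    """Write conformers to a V2000 SDF file (4-decimal coordinates)."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    try:
        for conf in conformers:
            mol = _conformer_to_mol(conf)
            try:
                Chem.SanitizeMol(mol)
            except Exception:  # geometry round-trip does not need valence fixing
                mol.UpdatePropertyCache(strict=False)
            mol.SetProp("_Name", conf.mol_id)
            mol.SetProp("energy", repr(conf.energy))
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str | Path) -> list[Conformer3D]:
    """Read a V2000 SDF file back into conformers.

    Raises :class:`SDFParseError` naming the index of the first molecule
    block RDKit cannot parse.
    """
    if Path(path).read_text().strip() == "":
        return []  # a valid file with zero molecule blocks
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    out: list[Conformer3D] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise SDFParseError(f"{path}: malformed molecule block at index {idx}")
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{idx}"
        energy = float(mol.GetProp("energy")) if mol.HasProp("energy") else 0.0
        out.append(_mol_to_conformer(mol, mol_id, energy))
    return out
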