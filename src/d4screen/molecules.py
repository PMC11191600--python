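"""Reading, standardizing and writing molecule libraries and score tables.

Molecules are carried around as :class:`MoleculeRecord` objects holding both
the structure string as supplied and its canonical form.  Standardization is
deliberately minimal — largest covalent fragment plus charge neutralization —
so that the same molecule spelled differently (salt forms, protonation
states, atom ordering) maps to one canonical string.  Tautomer
canonicalization is intentionally not applied.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")


class MoleculeError(ValueError):
    """Raised for unparseable structures or unusable libraries."""


@dataclass(frozen=True)
class MoleculeRecord:
    """An identified molecule with its canonical structure string.

    Attributes
    ----------
    mol_id:
        Unique identifier within a library.
    smiles_raw:
        The structure string exactly as supplied.
    smiles_canonical:
        RDKit canonical SMILES after standardization.
    source_tag:
        Free-text provenance label (library name etc.).
    """

    mol_id: str
    smiles_raw: str
    smiles_canonical: str
    source_tag: str = ""


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES of ``smiles``; raises :class:`MoleculeError` if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparseable structure: {smiles!r}")
    return Chem.MolToSmiles(mol)


_fragment_chooser = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()


def _standardize_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparseable structure: {smiles!r}")
    mol = _fragment_chooser.choose(mol)
    mol = _uncharger.uncharge(mol)
    return Chem.MolToSmiles(mol)


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Standardize a record: keep the largest covalent fragment, neutralize
    simple protonation states, emit the canonical string.

    Stereochemistry annotations present in the input are preserved.
    Idempotent: standardizing an already-standard record is a no-op.
    """
    try:
        canon = _standardize_smiles(record.smiles_raw)
    except MoleculeError as exc:
        raise MoleculeError(f"cannot standardize {record.mol_id}: {exc}") from exc
    return replace(record, smiles_canonical=canon)


def _unique_id(base: str, seen: dict[str, int]) -> str:
    """Resolve id collisions by appending -2, -3, ... (data is never dropped)."""
    if base not in seen:
        seen[base] = 1
        return base
    seen[base] += 1
    new = f"{base}-{seen[base]}"
    logger.warning("duplicate mol_id %r renamed to %r", base, new)
    return new


def _iter_smiles_list(path: Path) -> Iterable[tuple[str, str]]:
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{i + 1}"
            yield mol_id, smiles


def _iter_csv(path: Path) -> Iterable[tuple[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"mol_id", "smiles"} <= set(reader.fieldnames):
            raise MoleculeError(f"{path}: CSV must have columns mol_id, smiles")
        for row in reader:
            yield row["mol_id"], row["smiles"]


def _iter_sdf(path: Path, id_property: str | None) -> Iterable[tuple[str, str]]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            yield f"sdf{i + 1}", ""  # unparseable entry, skipped downstream
            continue
        if id_property and mol.HasProp(id_property):
            mol_id = mol.GetProp(id_property)
        elif mol.HasProp("_Name") and mol.GetProp("_Name"):
            mol_id = mol.GetProp("_Name")
        else:
            mol_id = f"sdf{i + 1}"
        yield mol_id, Chem.MolToSmiles(mol)


def load_library(
    path: str | Path,
    format: str | None = None,
    source_tag: str = "",
    id_property: str | None = None,
) -> list[MoleculeRecord]:
    """Load a molecule library from a SMILES list, CSV (mol_id, smiles) or SDF.

    Unparseable entries are counted, logged and skipped; a library with zero
    parseable molecules is a hard error.  Identifier collisions are resolved
    by suffixing ``-2``, ``-3``, ...  If ``format`` is omitted it is inferred
    from the file extension (.smi/.txt, .csv, .sdf).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".sdf": "sdf"}.get(path.suffix.lower(), "smiles-list")
    if format == "smiles-list":
        entries = _iter_smiles_list(path)
    elif format == "csv":
        entries = _iter_csv(path)
    elif format == "sdf":
        entries = _iter_sdf(path, id_property)
    else:
        raise ValueError(f"unknown format {format!r}")

    records: list[MoleculeRecord] = []
    seen: dict[str, int] = {}
    n_skipped = 0
    for mol_id, smiles in entries:
        try:
            canon = _standardize_smiles(smiles)
        except MoleculeError:
            n_skipped += 1
            logger.warning("skipping unparseable entry %r (%r)", mol_id, smiles)
            continue
        records.append(
            MoleculeRecord(
                mol_id=_unique_id(str(mol_id), seen),
                smiles_raw=smiles,
                smiles_canonical=canon,
                source_tag=source_tag,
            )
        )
    if n_skipped:
        logger.info("%s: skipped %d unparseable entries", path, n_skipped)
    if not records:
        raise MoleculeError(f"{path}: no parseable molecules")
    return records


def save_library(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write a library as CSV with columns mol_id, smiles (canonical forms)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mol_id", "smiles"])
        for rec in records:
            writer.writerow([rec.mol_id, rec.smiles_canonical])


def dedup_report(records: Sequence[MoleculeRecord]):
    """Canonical structures occurring under more than one id.

    Duplicate structures are retained in the library (screening decks
    legitimately contain duplicates); this report makes them visible.
    Returns a mapping canonical SMILES -> list of mol_ids, only for
    structures with >= 2 ids.
    """
    by_structure: dict[str, list[str]] = {}
    for rec in records:
        by_structure.setdefault(rec.smiles_canonical, []).append(rec.mol_id)
    return {smi: ids for smi, ids in by_structure.items() if len(ids) > 1}


def write_scores(scores, path: str | Path) -> None:
    """Write screening scores as CSV in rank order.

    Fixed header ``mol_id,activity_score,selectivity_score,passed_activity,
    passed_selectivity,rank``; byte-deterministic for identical input.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("scores must be non-empty")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["mol_id", "activity_score", "selectivity_score", "passed_activity", "passed_selectivity", "rank"]
        )
        for s in sorted(scores, key=lambda s: s.rank):
            writer.writerow(
                [
                    s.mol_id,
                    f"{s.activity_score:.6f}",
                    f"{s.selectivity_score:.6f}",
                    str(bool(s.passed_activity)),
                    str(bool(s.passed_selectivity)),
                    s.rank,
                ]
            )
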