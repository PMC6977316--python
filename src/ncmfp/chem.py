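"""Molecule parsing, preprocessing and compound-set I/O.

Molecules are carried as RDKit ``Mol`` objects throughout the package.
Aromaticity is perceived at parse time and substructure matching is
aromatic-strict (benzene never matches cyclohexane).  Stereochemistry is
parsed but ignored for canonical identity — the fingerprint is a 2D
descriptor.  Atom indices are 0-based everywhere, including the
scaffold-fragment connection-point reporting downstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdMolDescriptors

logger = logging.getLogger(__name__)

# RDKit is chatty on malformed records; failures are surfaced as exceptions
# or logged warnings by this module instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


class StructureParseError(ValueError):
    """Raised when a structure record cannot be parsed.

    Carries the offending record id so batch readers can report it.
    """

    def __init__(self, message: str, record_id: Optional[str] = None):
        super().__init__(message)
        self.record_id = record_id


class PreparationError(ValueError):
    """Raised when hydrogen addition / valence completion fails."""


@dataclass(frozen=True)
class AtomMapping:
    """An embedding of a pattern molecule into a target molecule.

    ``pairs[i]`` is the 0-based target atom index matched to pattern atom
    ``i``.  The mapping is injective by construction.
    """

    pairs: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def target_atoms(self) -> frozenset[int]:
        return frozenset(self.pairs)

    def inverse(self) -> dict[int, int]:
        """target atom index -> pattern atom index."""
        return {t: p for p, t in enumerate(self.pairs)}


@dataclass(frozen=True)
class PreparedMolecule:
    """A molecule readied for fingerprinting: explicit hydrogens, fixed
    0-based atom indices, molecular weight (average atomic masses, Da) and
    Hill-order formula."""

    mol: Chem.Mol
    molecular_weight: float
    molecular_formula: str

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()


@dataclass
class CompoundRecord:
    """One compound of a data set: structure plus optional labels."""

    id: str
    mol: Chem.Mol
    class_label: Optional[str] = None
    ic50: Optional[float] = None  # µmol
    activity: Optional[str] = None  # "active" | "inactive"


@dataclass
class ReadReport:
    """Bookkeeping of a compound-set read: kept + skipped + acyclic equals
    the number of input records."""

    kept: int = 0
    skipped: int = 0  # malformed records
    acyclic: int = 0  # parsed but ring-free, excluded
    skipped_ids: list[str] = field(default_factory=list)
    acyclic_ids: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.kept + self.skipped + self.acyclic


def parse_structure(text: str, fmt: str = "smiles",
                    record_id: Optional[str] = None) -> Chem.Mol:
    """Parse a SMILES string or a single SDF (V2000) record into a molecule.

    Aromaticity is perceived; malformed input raises
    :class:`StructureParseError` carrying ``record_id``.
    """
    if not text or not text.strip():
        raise StructureParseError("empty structure record", record_id)
    if fmt == "smiles":
        mol = Chem.MolFromSmiles(text)
    elif fmt == "sdf":
        mol = Chem.MolFromMolBlock(text)
    else:
        raise ValueError(f"unknown structure format: {fmt!r}")
    if mol is None:
        raise StructureParseError(
            f"could not parse {fmt} record: {text.strip().splitlines()[0]!r}",
            record_id,
        )
    return mol


def canonical_form(mol: Chem.Mol) -> str:
    """Canonical SMILES identity of a molecular graph.

    Invariant under atom reordering; stereochemistry is dropped (2D
    identity) and explicit hydrogens are folded back in.
    """
    stripped = Chem.RemoveHs(mol)
    return Chem.MolToSmiles(stripped, isomericSmiles=False)


def preprocess(mol: Chem.Mol) -> PreparedMolecule:
    """Fingerprint step one: make every hydrogen explicit, freeze 0-based
    atom indices, and compute molecular weight / Hill formula.

    Idempotent: preparing an already-prepared molecule changes nothing.
    """
    try:
        explicit = Chem.AddHs(mol)
        Chem.SanitizeMol(explicit)
    except Exception as exc:  # pragma: no cover - rdkit raises varied types
        raise PreparationError(f"cannot prepare molecule: {exc}") from exc
    mw = round(Descriptors.MolWt(explicit), 2)
    formula = rdMolDescriptors.CalcMolFormula(explicit)
    return PreparedMolecule(mol=explicit, molecular_weight=mw,
                            molecular_formula=formula)


def match_substructure(pattern: Chem.Mol,
                       target: PreparedMolecule | Chem.Mol,
                       max_matches: int = 100_000) -> list[AtomMapping]:
    """All subgraph-isomorphism embeddings of ``pattern`` into ``target``.

    Aromatic atoms and bonds match only aromatic counterparts; an empty
    list means no match.  Every symmetry image is returned (uniquify off),
    so automorphic embeddings are enumerable by the caller.
    """
    if pattern.GetNumAtoms() == 0:
        raise ValueError("pattern must contain at least one atom")
    mol = target.mol if isinstance(target, PreparedMolecule) else target
    matches = mol.GetSubstructMatches(pattern, uniquify=False,
                                      maxMatches=max_matches)
    return [AtomMapping(pairs=m) for m in matches]


def has_ring(mol: Chem.Mol) -> bool:
    return mol.GetRingInfo().NumRings() >= 1


def largest_component(mol: Chem.Mol) -> Chem.Mol:
    """Largest covalent component of a (possibly multi-fragment) record.

    Salt/solvate records are reduced to their biggest piece before the ring
    filter; single-component molecules pass through unchanged.
    """
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def _iter_raw_records(path: Path, fmt: str) -> Iterator[dict]:
    """Yield raw records as dicts with at least {id, source}, where source
    is either a smiles string or a molblock."""
    if fmt == "smi":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                rid = parts[1].strip() if len(parts) > 1 else f"record-{i}"
                yield {"id": rid, "smiles": parts[0]}
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            rid = f"record-{i}"
            if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name"):
                rid = mol.GetProp("_Name")
            yield {"id": rid, "mol": mol}
    elif fmt in ("csv", "tsv"):
        delim = "\t" if fmt == "tsv" else ","
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            if reader.fieldnames is None:
                return
            cols = {c.lower().strip(): c for c in reader.fieldnames}
            if "smiles" not in cols or "id" not in cols:
                raise ValueError(
                    f"{path}: need header columns 'id' and 'smiles'")
            for i, row in enumerate(reader):
                rec = {
                    "id": (row.get(cols["id"]) or f"record-{i}").strip(),
                    "smiles": (row.get(cols["smiles"]) or "").strip(),
                }
                for opt in ("class", "ic50", "activity"):
                    if opt in cols and row.get(cols[opt]) not in (None, ""):
                        rec[opt] = row[cols[opt]].strip()
                yield rec
    else:
        raise ValueError(f"unknown compound-set format: {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    return {"smi": "smi", "smiles": "smi", "sdf": "sdf", "mol": "sdf",
            "csv": "csv", "tsv": "tsv", "txt": "smi"}.get(suffix, "smi")


def read_compound_set(path, fmt: Optional[str] = None,
                      return_report: bool = False):
    """Read a compound set, applying the at-least-one-ring filter.

    Multi-component records are reduced to their largest covalent component
    first.  Malformed records are skipped with a WARNING and counted;
    ring-free compounds are excluded and counted separately.  Returns the
    surviving :class:`CompoundRecord` list (and the :class:`ReadReport`
    when ``return_report`` is true).
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read compound set: {path}")
    fmt = fmt or _infer_format(path)
    report = ReadReport()
    records: list[CompoundRecord] = []
    for raw in _iter_raw_records(path, fmt):
        rid = raw["id"]
        mol = raw.get("mol")
        if mol is None and "smiles" in raw:
            try:
                mol = parse_structure(raw["smiles"], "smiles", record_id=rid)
            except StructureParseError:
                mol = None
        if mol is None:
            report.skipped += 1
            report.skipped_ids.append(rid)
            logger.warning("skipping malformed record %r", rid)
            continue
        mol = largest_component(mol)
        if not has_ring(mol):
            report.acyclic += 1
            report.acyclic_ids.append(rid)
            logger.warning("excluding ring-free compound %r", rid)
            continue
        ic50 = float(raw["ic50"]) if "ic50" in raw else None
        records.append(CompoundRecord(
            id=rid, mol=mol,
            class_label=raw.get("class"),
            ic50=ic50,
            activity=raw.get("activity"),
        ))
        report.kept += 1
    if not records:
        logger.warning("no surviving records in %s", path)
    if return_report:
        return records, report
    return records


def write_compound_set(records: Sequence[CompoundRecord], path,
                       fmt: str = "tsv") -> None:
    """Write compounds as a TSV/CSV table (id, smiles, class, ic50, activity)
    or a SMILES line file."""
    path = Path(path)
    if fmt == "smi":
        with open(path, "w") as fh:
            for r in records:
                fh.write(f"{canonical_form(r.mol)}\t{r.id}\n")
        return
    delim = "\t" if fmt == "tsv" else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["id", "smiles", "class", "ic50", "activity"])
        for r in records:
            writer.writerow([
                r.id, canonical_form(r.mol),
                r.class_label if r.class_label is not None else "",
                r.ic50 if r.ic50 is not None else "",
                r.activity if r.activity is not None else "",
            ])
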