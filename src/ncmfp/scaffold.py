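"""Bemis-Murcko frameworks, ring pruning and leveled scaffold libraries.

The framework of a molecule keeps its rings, the linkers between rings and
any atom double-bonded to a kept atom; all other side-chain atoms are
removed.  Iteratively deleting one peripheral ring at a time yields a
hierarchy: a scaffold with ``r`` SSSR rings sits at level ``r - 1``, so
level 0 scaffolds are single rings.  Per structural class, the scaffolds
observed at each level across a set of representative compounds form the
class scaffold library; the union over classes is the scaffold block of
the fingerprint.

Pruning enumerates *all* one-ring-removal parents (a scaffold network, not
a single canonical chain); chemically invalid intermediates are discarded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem import (CompoundRecord, PreparedMolecule, canonical_form,
                   has_ring, preprocess)

logger = logging.getLogger(__name__)


class NoScaffoldError(ValueError):
    """Raised when a ring-free molecule is asked for its scaffold."""


@dataclass(frozen=True)
class Scaffold:
    """One scaffold s(class, level, index): canonical form is its identity.

    ``level == ring_count - 1`` by construction; ``index_in_level`` is the
    0-based rank under lexicographic canonical-form ordering, so indices
    are reproducible across runs.
    """

    smiles: str
    level: int
    ring_count: int
    source_class: Optional[str] = None
    index_in_level: int = 0

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - stored forms are canonical
            raise ValueError(f"stored scaffold is unparseable: {self.smiles}")
        return m


def _ring_count(mol: Chem.Mol) -> int:
    return len(Chem.GetSSSR(mol))


def murcko_framework(m: PreparedMolecule | Chem.Mol) -> Chem.Mol:
    """Bemis-Murcko framework: rings + inter-ring linkers + exocyclic and
    terminal double bonds attached to them; side chains removed.

    Raises :class:`NoScaffoldError` on ring-free input.  Idempotent.
    """
    mol = m.mol if isinstance(m, PreparedMolecule) else m
    mol = Chem.RemoveHs(mol)
    if not has_ring(mol):
        raise NoScaffoldError("molecule has no ring, no scaffold exists")
    framework = MurckoScaffold.GetScaffoldForMol(mol)
    if framework is None or framework.GetNumAtoms() == 0:  # pragma: no cover
        raise NoScaffoldError("framework extraction produced no atoms")
    Chem.SanitizeMol(framework)
    return framework


def prune_one_ring(scaffold: Chem.Mol) -> list[Chem.Mol]:
    """All valid scaffolds obtained by deleting one peripheral SSSR ring.

    Atoms exclusive to the removed ring are deleted, then dangling linker
    atoms no longer connecting two rings are cleaned up by re-extracting
    the framework.  Results are deduplicated by canonical form and each
    has exactly one ring fewer; a single-ring input returns the empty
    list (pruning terminates).  Removals that disconnect the scaffold or
    leave an unsanitizable fragment are discarded.
    """
    n_rings = _ring_count(scaffold)
    if n_rings <= 1:
        return []
    rings = scaffold.GetRingInfo().AtomRings()
    out: dict[str, Chem.Mol] = {}
    for i, ring in enumerate(rings):
        shared = set()
        for j, other in enumerate(rings):
            if j != i:
                shared.update(other)
        exclusive = [a for a in ring if a not in shared]
        if not exclusive:
            continue  # ring fully embedded in others (bridged core)
        doomed = set(exclusive)
        # take along non-ring substituents (e.g. exocyclic =O) that would
        # otherwise be stranded by the ring removal
        changed = True
        while changed:
            changed = False
            for atom in scaffold.GetAtoms():
                idx = atom.GetIdx()
                if idx in doomed or atom.IsInRing():
                    continue
                nbrs = [n.GetIdx() for n in atom.GetNeighbors()
                        if n.GetAtomicNum() > 1]
                if nbrs and all(n in doomed for n in nbrs):
                    doomed.add(idx)
                    changed = True
        pruned = _remove_atoms(scaffold, doomed)
        if pruned is None:
            logger.debug("discarding chemically invalid pruning of ring %d", i)
            continue
        if len(Chem.GetMolFrags(pruned)) != 1:
            continue  # removing a central ring disconnects the scaffold
        if not has_ring(pruned):
            continue
        cleaned = murcko_framework(pruned)
        if _ring_count(cleaned) != n_rings - 1:
            continue  # bridged/fused removal collapsed >1 ring
        out[canonical_form(cleaned)] = cleaned
    return [out[k] for k in sorted(out)]


def _remove_atoms(mol: Chem.Mol, atoms: Iterable[int]) -> Optional[Chem.Mol]:
    """Delete atoms from a copy and re-perceive aromaticity.

    Removal is attempted on the aromatic form first: rings that survive
    intact (e.g. the remaining ring of naphthalene) keep their aromaticity
    regardless of which kekule structure a kekulized copy would have
    frozen.  If the aromatic remnant cannot be sanitized, the removal is
    retried on a kekulized copy; if that also fails the pruning is
    chemically invalid and discarded (None).
    """
    doomed = sorted(atoms, reverse=True)
    for kekulize in (False, True):
        rw = Chem.RWMol(mol)
        if kekulize:
            try:
                Chem.Kekulize(rw, clearAromaticFlags=True)
            except Chem.KekulizeException:
                return None
        for idx in doomed:
            rw.RemoveAtom(idx)
        try:
            pruned = rw.GetMol()
            Chem.SanitizeMol(pruned)
            return pruned
        except Exception:
            continue
    return None


def enumerate_levels(m: PreparedMolecule | Chem.Mol) -> dict[int, list[Chem.Mol]]:
    """Full pruning hierarchy of a molecule: level -> scaffolds.

    Breadth-first from the Bemis-Murcko framework down to single rings,
    deduplicated by canonical form within each level.  ``level =
    ring_count - 1``; level 0 is always non-empty for ringed input.
    """
    root = murcko_framework(m)
    seen: dict[str, Chem.Mol] = {canonical_form(root): root}
    frontier = [root]
    while frontier:
        nxt = []
        for scf in frontier:
            for child in prune_one_ring(scf):
                key = canonical_form(child)
                if key not in seen:
                    seen[key] = child
                    nxt.append(child)
        frontier = nxt
    levels: dict[int, list[Chem.Mol]] = {}
    for key in sorted(seen):
        scf = seen[key]
        levels.setdefault(_ring_count(scf) - 1, []).append(scf)
    return levels


@dataclass
class ScaffoldLibrary:
    """Class-wise leveled scaffold library.

    ``scaffolds[class][level]`` is an ordered, per-(class, level)
    deduplicated list of :class:`Scaffold`.  Cross-class duplicates are
    retained: per-level totals are row sums over classes.
    """

    classes: list[str]
    scaffolds: dict[str, dict[int, list[Scaffold]]]
    provenance: dict = field(default_factory=dict)

    @property
    def levels(self) -> list[int]:
        out = sorted({lv for per in self.scaffolds.values() for lv in per})
        return out

    def at_level(self, level: int, class_id: Optional[str] = None) -> list[Scaffold]:
        if class_id is not None:
            return list(self.scaffolds.get(class_id, {}).get(level, []))
        out: list[Scaffold] = []
        for cls in self.classes:
            out.extend(self.scaffolds[cls].get(level, []))
        return out

    def all_scaffolds(self, levels: Optional[Sequence[int]] = None) -> list[Scaffold]:
        """Scaffolds in library order: class, then level, then index."""
        out: list[Scaffold] = []
        for cls in self.classes:
            for lv in sorted(self.scaffolds[cls]):
                if levels is None or lv in levels:
                    out.extend(self.scaffolds[cls][lv])
        return out

    def counts(self) -> dict[str, dict[int, int]]:
        return {cls: {lv: len(scfs) for lv, scfs in per.items()}
                for cls, per in self.scaffolds.items()}

    def level_totals(self) -> dict[int, int]:
        totals: dict[int, int] = {}
        for per in self.scaffolds.values():
            for lv, scfs in per.items():
                totals[lv] = totals.get(lv, 0) + len(scfs)
        return dict(sorted(totals.items()))

    def to_json(self, path) -> None:
        payload = {
            "classes": {
                cls: {str(lv): [{"smiles": s.smiles, "index": s.index_in_level}
                                for s in scfs]
                      for lv, scfs in self.scaffolds[cls].items()}
                for cls in self.classes
            },
            "metadata": {"provenance": self.provenance,
                         "atom_indexing": "0-based",
                         "format_version": 1},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "ScaffoldLibrary":
        payload = json.loads(Path(path).read_text())
        classes = list(payload["classes"])
        scaffolds: dict[str, dict[int, list[Scaffold]]] = {}
        for cid, per in payload["classes"].items():
            scaffolds[cid] = {}
            for lv, items in per.items():
                level = int(lv)
                scaffolds[cid][level] = [
                    Scaffold(smiles=it["smiles"], level=level,
                             ring_count=level + 1, source_class=cid,
                             index_in_level=it["index"])
                    for it in items
                ]
        return cls(classes=classes, scaffolds=scaffolds,
                   provenance=payload.get("metadata", {}).get("provenance", {}))


def build_library(compounds: Sequence[CompoundRecord],
                  levels: Iterable[int] = (0, 1, 2, 3)) -> ScaffoldLibrary:
    """Build the class-wise scaffold library of a labeled compound set.

    For each class the pruning hierarchies of its compounds are pooled,
    restricted to the requested levels, deduplicated per (class, level)
    and ordered lexicographically by canonical form so indices are stable.
    Every record must carry a class label and at least one ring.
    """
    levels = sorted(set(int(v) for v in levels))
    unlabeled = [r.id for r in compounds if r.class_label is None]
    if unlabeled:
        raise ValueError(f"records without class label: {unlabeled[:10]}")
    per_class: dict[str, dict[int, set[str]]] = {}
    class_sizes: dict[str, int] = {}
    classes: list[str] = []
    for rec in compounds:
        cls = rec.class_label
        if cls not in per_class:
            per_class[cls] = {lv: set() for lv in levels}
            classes.append(cls)
            class_sizes[cls] = 0
        class_sizes[cls] += 1
        hierarchy = enumerate_levels(preprocess(rec.mol))
        for lv in levels:
            for scf in hierarchy.get(lv, []):
                per_class[cls][lv].add(canonical_form(scf))
    scaffolds: dict[str, dict[int, list[Scaffold]]] = {}
    for cls in classes:
        scaffolds[cls] = {}
        for lv in levels:
            ordered = sorted(per_class[cls][lv])
            scaffolds[cls][lv] = [
                Scaffold(smiles=smi, level=lv, ring_count=lv + 1,
                         source_class=cls, index_in_level=k)
                for k, smi in enumerate(ordered)
            ]
    return ScaffoldLibrary(
        classes=classes, scaffolds=scaffolds,
        provenance={"source_compound_counts": class_sizes,
                    "levels": levels},
    )
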