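"""The scaffold / connection-point / fragment fingerprint engine.

A feature dictionary fixes the bit layout: an ordered scaffold block (a
scaffold library, levels 1-2 by default), an ordered block of
scaffold-fragment connection points (SFCP: a scaffold atom position at
which a fragment was observed attached), and an ordered fragment block
(distinct fragment canonical forms, indexed by ascending molecular
weight).  Fingerprinting a query then runs six steps: (I) hydrogen
completion and index assignment, (II) substructure matching of every
dictionary scaffold, (III) fragment generation by deleting the matched
scaffold atoms, (IV) connection-point assignment on the scaffold's own
canonical atom numbering, (V) fragment identification by canonical-form
lookup, (VI) emission of the fixed-length bit string.

Connection points are made query-independent by symmetry reduction: among
all automorphism-equivalent embeddings of a scaffold onto the same query
atoms, the embedding giving the lexicographically smallest tuple of
canonical positions is used.  Features observed on a query but absent
from the dictionary are dropped and counted, keeping the vector length
fixed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem import (AtomMapping, CompoundRecord, PreparedMolecule,
                   canonical_form, has_ring, match_substructure, preprocess)
from .scaffold import NoScaffoldError, Scaffold, ScaffoldLibrary

logger = logging.getLogger(__name__)

ATTACHMENT = "*"  # dummy-atom attachment marker in fragment forms


@dataclass(frozen=True)
class SFCPFeature:
    """A connection point: scaffold block position + canonical atom index
    on that scaffold (0-based, on the scaffold's own canonical ordering)."""

    scaffold_pos: int
    atom_position: int


@dataclass(frozen=True)
class FragmentRecord:
    """A dictionary fragment: canonical form with attachment marker(s),
    molecular weight excluding the marker (Da), and 1-based index assigned
    by ascending weight (ties by canonical form)."""

    smiles: str
    mw: float
    index: int


@dataclass(frozen=True)
class FragmentInstance:
    """One fragment cut from a query: canonical form, weight, number of
    occurrences, and the query atoms (scaffold side) it was attached to."""

    smiles: str
    mw: float
    count: int
    attach_atoms: tuple[int, ...]  # scaffold-side atom indices in the query


@dataclass(frozen=True)
class ScaffoldMatch:
    """One match site of a dictionary scaffold on a query: the
    symmetry-reduced representative embedding and its connection points."""

    scaffold: Scaffold
    scaffold_pos: int
    mapping: AtomMapping
    sfcp_positions: tuple[int, ...]  # sorted canonical positions, one per cut


class FeatureDictionary:
    """Fixed bit layout: scaffold block, SFCP block, fragment block.

    Deterministic given (library, reference compounds); serializable to a
    versioned JSON file whose checksum travels with every fingerprint.
    """

    def __init__(self, scaffolds: Sequence[Scaffold],
                 sfcps: Sequence[SFCPFeature],
                 fragments: Sequence[FragmentRecord],
                 metadata: Optional[dict] = None):
        self.scaffolds = list(scaffolds)
        self.sfcps = list(sfcps)
        self.fragments = list(fragments)
        self.metadata = dict(metadata or {})
        self._scaffold_bit = {s.smiles: i for i, s in enumerate(self.scaffolds)}
        ns = len(self.scaffolds)
        self._sfcp_bit = {(f.scaffold_pos, f.atom_position): ns + i
                          for i, f in enumerate(self.sfcps)}
        nsf = ns + len(self.sfcps)
        self._fragment_bit = {f.smiles: nsf + i
                              for i, f in enumerate(self.fragments)}
        self._mols: list[Chem.Mol] = [s.mol() for s in self.scaffolds]
        self._ranks: list[tuple[int, ...]] = [
            tuple(Chem.CanonicalRankAtoms(m, breakTies=True))
            for m in self._mols
        ]

    @property
    def n_bits(self) -> int:
        return len(self.scaffolds) + len(self.sfcps) + len(self.fragments)

    @property
    def block_sizes(self) -> tuple[int, int, int]:
        return (len(self.scaffolds), len(self.sfcps), len(self.fragments))

    def scaffold_bit(self, pos: int) -> int:
        return pos

    def sfcp_bit(self, feature: SFCPFeature) -> Optional[int]:
        return self._sfcp_bit.get((feature.scaffold_pos, feature.atom_position))

    def fragment_record(self, smiles: str) -> Optional[FragmentRecord]:
        bit = self._fragment_bit.get(smiles)
        if bit is None:
            return None
        return self.fragments[bit - len(self.scaffolds) - len(self.sfcps)]

    def fragment_bit(self, smiles: str) -> Optional[int]:
        return self._fragment_bit.get(smiles)

    def checksum(self) -> str:
        payload = json.dumps(self._blocks_payload(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def _blocks_payload(self) -> dict:
        return {
            "scaffolds": [{"smiles": s.smiles, "class": s.source_class,
                           "level": s.level, "index": s.index_in_level}
                          for s in self.scaffolds],
            "sfcps": [[f.scaffold_pos, f.atom_position] for f in self.sfcps],
            "fragments": [{"smiles": f.smiles, "mw": f.mw, "index": f.index}
                          for f in self.fragments],
        }

    def to_json(self, path) -> None:
        payload = self._blocks_payload()
        payload["metadata"] = {
            **self.metadata,
            "layout": "scaffold_block || sfcp_block || fragment_block",
            "atom_indexing": "0-based canonical scaffold order",
            "n_bits": self.n_bits,
            "checksum": self.checksum(),
            "format_version": 1,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "FeatureDictionary":
        payload = json.loads(Path(path).read_text())
        scaffolds = [Scaffold(smiles=s["smiles"], level=s["level"],
                              ring_count=s["level"] + 1,
                              source_class=s.get("class"),
                              index_in_level=s["index"])
                     for s in payload["scaffolds"]]
        sfcps = [SFCPFeature(*pair) for pair in payload["sfcps"]]
        fragments = [FragmentRecord(smiles=f["smiles"], mw=f["mw"],
                                    index=f["index"])
                     for f in payload["fragments"]]
        return cls(scaffolds, sfcps, fragments,
                   metadata=payload.get("metadata", {}))


@dataclass
class Fingerprint:
    """Fixed-length bit string plus per-bit provenance and quality flags."""

    bits: np.ndarray  # uint8 vector of length dictionary.n_bits
    provenance: dict[int, tuple[str, str]] = field(default_factory=dict)
    no_scaffold_match: bool = False
    unknown_fragments: int = 0
    unknown_sfcps: int = 0
    dictionary_checksum: str = ""

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[0])

    @property
    def set_positions(self) -> list[int]:
        return np.flatnonzero(self.bits).tolist()

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()


def _heavy_cut_bonds(q: Chem.Mol, mapped: frozenset[int]) -> list[tuple[int, int, int]]:
    """Bonds crossing the matched scaffold boundary, heavy atoms only.

    Returns (bond index, scaffold-side atom, fragment-side atom) triples.
    """
    cuts = []
    for bond in q.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        ai, bi = a.GetIdx(), b.GetIdx()
        inside_a, inside_b = ai in mapped, bi in mapped
        if inside_a != inside_b:
            s, t = (ai, bi) if inside_a else (bi, ai)
            cuts.append((bond.GetIdx(), s, t))
    return cuts


def _site_sfcp(q: Chem.Mol, embeddings: list[AtomMapping],
               ranks: tuple[int, ...]) -> tuple[AtomMapping, tuple[int, ...]]:
    """Symmetry-reduce one match site.

    All embeddings cover the same query atoms; pick the one whose sorted
    tuple of connection-point canonical positions is lexicographically
    smallest, making SFCP output independent of query atom order.
    """
    mapped = embeddings[0].target_atoms()
    cuts = _heavy_cut_bonds(q, mapped)
    if not cuts:
        return embeddings[0], ()
    best_mapping, best_tuple = None, None
    for emb in embeddings:
        inv = emb.inverse()
        positions = tuple(sorted(ranks[inv[s]] for _, s, _ in cuts))
        if best_tuple is None or positions < best_tuple:
            best_tuple, best_mapping = positions, emb
    return best_mapping, best_tuple


def match_scaffolds(q: PreparedMolecule,
                    dictionary: FeatureDictionary) -> list[ScaffoldMatch]:
    """Fingerprint step two: find every dictionary scaffold contained in
    the query, one symmetry-reduced representative embedding per match
    site (distinct set of covered query atoms).

    Raises :class:`NoScaffoldError` on ring-free queries — the fingerprint
    is defined only for compounds with at least one ring.
    """
    if not has_ring(q.mol):
        raise NoScaffoldError(
            "fingerprint requires a compound with at least one ring")
    out: list[ScaffoldMatch] = []
    for pos, scaffold in enumerate(dictionary.scaffolds):
        pattern = dictionary._mols[pos]
        if not q.mol.HasSubstructMatch(pattern):
            continue
        embeddings = match_substructure(pattern, q)
        sites: dict[frozenset[int], list[AtomMapping]] = {}
        for emb in embeddings:
            sites.setdefault(emb.target_atoms(), []).append(emb)
        ranks = dictionary._ranks[pos]
        for atoms in sorted(sites, key=lambda s: tuple(sorted(s))):
            mapping, positions = _site_sfcp(q.mol, sites[atoms], ranks)
            out.append(ScaffoldMatch(scaffold=scaffold, scaffold_pos=pos,
                                     mapping=mapping,
                                     sfcp_positions=positions))
    return out


def generate_fragments(q: PreparedMolecule,
                       mapping: AtomMapping) -> list[FragmentInstance]:
    """Fingerprint step three: delete the matched scaffold atoms; every
    remaining connected heavy-atom component is a fragment, with a dummy
    marker atom at each broken bond.  Duplicate canonical forms collapse
    into one instance with an occurrence count; output is sorted by
    ascending molecular weight (marker excluded), ties by canonical form.
    """
    mol = q.mol if isinstance(q, PreparedMolecule) else q
    mapped = mapping.target_atoms()
    cuts = _heavy_cut_bonds(mol, mapped)
    if not cuts:
        return []
    bond_ids = [c[0] for c in cuts]
    # label dummies 1..k so each fragment can be traced to its cut bonds
    labels = [(k + 1, k + 1) for k in range(len(cuts))]
    fragged = Chem.FragmentOnBonds(mol, bond_ids, addDummies=True,
                                   dummyLabels=labels)
    frag_atom_lists: list[tuple[int, ...]] = []
    frag_mols = Chem.GetMolFrags(fragged, asMols=True, sanitizeFrags=False,
                                 fragsMolAtomMapping=frag_atom_lists)
    n_orig = mol.GetNumAtoms()
    grouped: dict[str, dict] = {}
    for fmol, atom_ids in zip(frag_mols, frag_atom_lists):
        originals = [a for a in atom_ids if a < n_orig]
        if any(a in mapped for a in originals):
            continue  # the scaffold-side piece
        attach = []
        for atom in fmol.GetAtoms():
            if atom.GetAtomicNum() == 0 and atom.GetIsotope() > 0:
                _, s, _ = cuts[atom.GetIsotope() - 1]
                attach.append(s)
                atom.SetIsotope(0)
        try:
            Chem.SanitizeMol(fmol)
        except Exception:  # pragma: no cover - cut pieces are valid radicals
            logger.warning("unsanitizable fragment skipped")
            continue
        smi = Chem.MolToSmiles(Chem.RemoveHs(fmol), isomericSmiles=False)
        mw = round(Descriptors.MolWt(fmol), 2)
        entry = grouped.setdefault(smi, {"mw": mw, "count": 0, "attach": []})
        entry["count"] += 1
        entry["attach"].extend(attach)
    out = [FragmentInstance(smiles=smi, mw=e["mw"], count=e["count"],
                            attach_atoms=tuple(e["attach"]))
           for smi, e in grouped.items()]
    out.sort(key=lambda f: (f.mw, f.smiles))
    return out


def assign_sfcp(scaffold_mol: Chem.Mol, mapping: AtomMapping,
                fragments: Sequence[FragmentInstance],
                ranks: Optional[Sequence[int]] = None) -> list[tuple[str, int]]:
    """Fingerprint step four: report, per fragment occurrence, the
    canonical scaffold atom position it is attached to.

    ``mapping`` should be the symmetry-reduced representative embedding
    (as produced by :func:`match_scaffolds`) so positions are
    query-independent.  Returns (fragment canonical form, position) pairs.
    """
    if ranks is None:
        ranks = tuple(Chem.CanonicalRankAtoms(scaffold_mol, breakTies=True))
    inv = mapping.inverse()
    out = []
    for frag in fragments:
        for s_atom in frag.attach_atoms:
            out.append((frag.smiles, ranks[inv[s_atom]]))
    return out


def identify_fragment(fragment: FragmentInstance | str,
                      dictionary: FeatureDictionary) -> Optional[int]:
    """Fingerprint step five: exact canonical-form lookup of a fragment in
    the dictionary; ``None`` if the fragment is unknown."""
    smi = fragment if isinstance(fragment, str) else fragment.smiles
    rec = dictionary.fragment_record(smi)
    return rec.index if rec is not None else None


def compute_ncmfp(q: PreparedMolecule, dictionary: FeatureDictionary,
                  multi_scaffold: bool = True) -> Fingerprint:
    """Run the six fingerprint steps and emit the fixed-length bit string.

    One bit per matched scaffold, per identified connection point and per
    identified fragment; layout is scaffold block, then SFCP block, then
    fragment block.  With ``multi_scaffold=False`` only the largest
    matched scaffold (most rings, then most atoms, then library order)
    contributes.  Deterministic and invariant to query atom ordering.
    """
    matches = match_scaffolds(q, dictionary)
    bits = np.zeros(dictionary.n_bits, dtype=np.uint8)
    fp = Fingerprint(bits=bits, dictionary_checksum=dictionary.checksum())
    if not matches:
        fp.no_scaffold_match = True
        return fp
    if not multi_scaffold:
        best = max(matches, key=lambda m: (m.scaffold.ring_count,
                                           m.scaffold.mol().GetNumAtoms(),
                                           -m.scaffold_pos))
        matches = [m for m in matches if m.scaffold_pos == best.scaffold_pos]
    for match in matches:
        bit = dictionary.scaffold_bit(match.scaffold_pos)
        bits[bit] = 1
        fp.provenance[bit] = ("scaffold", match.scaffold.smiles)
        fragments = generate_fragments(q, match.mapping)
        ranks = dictionary._ranks[match.scaffold_pos]
        pairs = assign_sfcp(dictionary._mols[match.scaffold_pos],
                            match.mapping, fragments, ranks=ranks)
        for _, position in pairs:
            feature = SFCPFeature(scaffold_pos=match.scaffold_pos,
                                  atom_position=position)
            sbit = dictionary.sfcp_bit(feature)
            if sbit is None:
                fp.unknown_sfcps += 1
                continue
            bits[sbit] = 1
            fp.provenance[sbit] = (
                "sfcp", f"{match.scaffold.smiles}@{position}")
        for frag in fragments:
            fbit = dictionary.fragment_bit(frag.smiles)
            if fbit is None:
                fp.unknown_fragments += frag.count
                continue
            bits[fbit] = 1
            fp.provenance[fbit] = ("fragment", frag.smiles)
    return fp


def build_feature_dictionary(lib: ScaffoldLibrary,
                             reference: Sequence[CompoundRecord],
                             levels: Optional[Iterable[int]] = None
                             ) -> FeatureDictionary:
    """Construct the fixed bit layout from a scaffold library and a
    reference compound set.

    The scaffold block is the library in its deterministic order
    (restricted to ``levels`` if given).  Steps II-IV are run over every
    reference compound; every observed (scaffold, connection point) and
    every distinct fragment canonical form populate the SFCP and fragment
    blocks.  Fragment indices are 1-based by ascending molecular weight.
    """
    scaffolds = lib.all_scaffolds(None if levels is None else sorted(levels))
    if not scaffolds:
        raise ValueError("scaffold library is empty at the requested levels")
    skeleton = FeatureDictionary(scaffolds, [], [])
    sfcp_set: set[tuple[int, int]] = set()
    fragment_mw: dict[str, float] = {}
    for rec in reference:
        prepared = preprocess(rec.mol)
        for match in match_scaffolds(prepared, skeleton):
            fragments = generate_fragments(prepared, match.mapping)
            for position in match.sfcp_positions:
                sfcp_set.add((match.scaffold_pos, position))
            for frag in fragments:
                fragment_mw.setdefault(frag.smiles, frag.mw)
    sfcps = [SFCPFeature(scaffold_pos=p, atom_position=a)
             for p, a in sorted(sfcp_set)]
    ordered = sorted(fragment_mw.items(), key=lambda kv: (kv[1], kv[0]))
    fragments = [FragmentRecord(smiles=smi, mw=mw, index=i + 1)
                 for i, (smi, mw) in enumerate(ordered)]
    return FeatureDictionary(
        scaffolds, sfcps, fragments,
        metadata={"n_reference_compounds": len(reference),
                  "library_levels": sorted(levels) if levels is not None
                  else lib.levels},
    )


def fingerprint_compounds(records: Sequence[CompoundRecord],
                          dictionary: FeatureDictionary,
                          multi_scaffold: bool = True,
                          on_error: str = "raise"
                          ) -> list[tuple[str, Fingerprint]]:
    """Fingerprint a compound set; ``on_error='skip'`` logs and drops
    ring-free queries instead of raising."""
    out = []
    for rec in records:
        try:
            fp = compute_ncmfp(preprocess(rec.mol), dictionary,
                               multi_scaffold=multi_scaffold)
        except NoScaffoldError:
            if on_error == "skip":
                logger.warning("skipping ring-free compound %r", rec.id)
                continue
            raise
        out.append((rec.id, fp))
    return out


def write_fingerprints(fps: Sequence[tuple[str, Fingerprint]], path,
                       fmt: str = "bits") -> None:
    """Write fingerprints as TSV: id, bit string (or hex-packed), with the
    dictionary checksum recorded in a header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        if fps:
            fh.write(f"# dictionary_checksum={fps[0][1].dictionary_checksum} "
                     f"n_bits={fps[0][1].n_bits} encoding={fmt}\n")
        for rid, fp in fps:
            value = fp.to_hex() if fmt == "hex" else fp.to_bitstring()
            fh.write(f"{rid}\t{value}\n")


def read_fingerprints(path) -> list[tuple[str, np.ndarray]]:
    """Read a fingerprint TSV (id, 0/1 bit string) from any generator."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rid, bitstring = line.split("\t")
            out.append((rid, np.frombuffer(
                bitstring.encode(), dtype=np.uint8) - ord("0")))
    return out
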