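"""Seeded synthetic compound sets for end-to-end pipeline testing.

Each toy class is a distinct single-ring system decorated at free-valence
positions with small fragments carrying attachment markers.  A planted
activity rule — presence of one designated marker fragment — labels the
compounds, optionally flipped by Bernoulli noise.  Because every class
base is a single ring, building a level-0 scaffold library from a
generated set recovers exactly the class bases, and every decoration is
recoverable by scaffold-removal fragment generation, so the whole
fingerprint pipeline round-trips exactly.

These are test fixtures echoing class-structured natural-compound
collections at toy scale, not chemistry claims; all randomness flows from
the single spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem import CompoundRecord, canonical_form, parse_structure, preprocess
from .fingerprint import generate_fragments, match_scaffolds, FeatureDictionary

# Distinct single-ring systems; single rings make level-0 library
# round-trips exact (a multi-ring base would collapse onto its sub-rings).
RING_CATALOG: list[tuple[str, str]] = [
    ("benzenoid", "c1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("thiophene", "c1ccsc1"),
    ("furan", "c1ccoc1"),
    ("pyrimidine", "c1cncnc1"),
    ("pyrazine", "c1cnccn1"),
    ("thiazole", "c1cscn1"),
    ("cyclohexane", "C1CCCCC1"),
    ("piperidine", "C1CCNCC1"),
    ("oxane", "C1CCOCC1"),
]

DEFAULT_FRAGMENT_POOL: list[str] = ["*C", "*O", "*Cl", "*N", "*OC"]


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a synthetic compound set.

    ``active_fragment`` defines the planted rule: a compound is active iff
    that fragment is attached to its class ring system (decidable from the
    structure alone); observed labels are the rule XOR Bernoulli(noise).
    """

    classes: tuple[tuple[str, str], ...]  # (class id, base ring smiles)
    fragment_pool: tuple[str, ...]
    active_fragment: str
    noise_rate: float = 0.0
    seed: int = 0

    def as_dict(self) -> dict:
        return {"classes": [list(c) for c in self.classes],
                "fragment_pool": list(self.fragment_pool),
                "active_fragment": self.active_fragment,
                "noise_rate": self.noise_rate, "seed": self.seed}


def make_toy_spec(n_classes: int, seed: int,
                  noise_rate: float = 0.0) -> ToySpec:
    """Deterministic toy spec: ``n_classes`` distinct ring systems drawn
    from the built-in catalog and a seeded fragment-pool ordering whose
    first element is the planted active fragment."""
    if not 1 <= n_classes <= len(RING_CATALOG):
        raise ValueError(
            f"n_classes must be in 1..{len(RING_CATALOG)}, got {n_classes}")
    rng = np.random.default_rng(seed)
    base_idx = rng.choice(len(RING_CATALOG), size=n_classes, replace=False)
    classes = tuple(RING_CATALOG[i] for i in sorted(base_idx))
    pool = list(DEFAULT_FRAGMENT_POOL)
    rng.shuffle(pool)
    return ToySpec(classes=classes, fragment_pool=tuple(pool),
                   active_fragment=pool[0], noise_rate=float(noise_rate),
                   seed=int(seed))


def free_positions(scaffold_smiles: str) -> list[int]:
    """Canonical atom positions of a scaffold with at least one hydrogen
    available for substitution."""
    mol = Chem.MolFromSmiles(scaffold_smiles)
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    return sorted(ranks[a.GetIdx()] for a in mol.GetAtoms()
                  if a.GetTotalNumHs() >= 1)


def decorate(scaffold_smiles: str, fragments: Sequence[str],
             positions: Sequence[int]) -> str:
    """Attach marker fragments to a scaffold at canonical atom positions.

    Positions refer to the scaffold's canonical atom ordering (the same
    convention the fingerprint's connection points use), so a decoration
    round-trips: the built molecule's fragments and connection points are
    recoverable by scaffold matching and fragment generation.
    """
    if len(fragments) != len(positions):
        raise ValueError("fragments and positions must pair up")
    scaffold = Chem.MolFromSmiles(scaffold_smiles)
    if scaffold is None:
        raise ValueError(f"bad scaffold smiles: {scaffold_smiles!r}")
    ranks = list(Chem.CanonicalRankAtoms(scaffold, breakTies=True))
    rank_to_idx = {r: i for i, r in enumerate(ranks)}
    available = {a.GetIdx(): a.GetTotalNumHs() for a in scaffold.GetAtoms()}
    rw = Chem.RWMol(scaffold)
    for frag_smi, pos in zip(fragments, positions):
        if pos not in rank_to_idx:
            raise ValueError(f"position {pos} is not a scaffold atom")
        target = rank_to_idx[pos]
        if available[target] < 1:
            raise ValueError(
                f"valence overflow at scaffold position {pos}")
        frag = Chem.MolFromSmiles(frag_smi)
        if frag is None:
            raise ValueError(f"bad fragment smiles: {frag_smi!r}")
        dummies = [a.GetIdx() for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise ValueError(
                f"fragment needs exactly one attachment marker: {frag_smi!r}")
        anchor = frag.GetAtomWithIdx(dummies[0]).GetNeighbors()[0].GetIdx()
        offset = rw.GetNumAtoms()
        rw.InsertMol(frag)
        rw.AddBond(target, offset + anchor, Chem.BondType.SINGLE)
        rw.RemoveAtom(offset + dummies[0])
        t_atom = rw.GetAtomWithIdx(target)
        if t_atom.GetNumExplicitHs() > 0:
            t_atom.SetNumExplicitHs(t_atom.GetNumExplicitHs() - 1)
        available[target] -= 1
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return canonical_form(mol)


def evaluate_planted_rule(mol: Chem.Mol, spec: ToySpec) -> bool:
    """Decide the planted rule from structure alone: does removing any
    matching class base scaffold expose the designated active fragment?"""
    active = canonical_form(Chem.MolFromSmiles(spec.active_fragment))
    bases = FeatureDictionary(
        scaffolds=[_base_scaffold(cid, smi) for cid, smi in spec.classes],
        sfcps=[], fragments=[])
    prepared = preprocess(mol)
    for match in match_scaffolds(prepared, bases):
        frags = generate_fragments(prepared, match.mapping)
        if any(f.smiles == active for f in frags):
            return True
    return False


def _base_scaffold(class_id: str, smiles: str):
    from .scaffold import Scaffold
    canon = canonical_form(Chem.MolFromSmiles(smiles))
    return Scaffold(smiles=canon, level=0, ring_count=1,
                    source_class=class_id, index_in_level=0)


def generate_dataset(spec: ToySpec, n: int) -> list[CompoundRecord]:
    """Generate ``n`` labeled compounds under the spec.

    Classes are filled round-robin (balanced within one compound) and
    rule-active / rule-inactive structures alternate within each class.
    Every compound is substituted at a fixed "pharmacophore slot" (the
    class ring's first free position): actives carry the designated
    fragment there, inactives one of two slot decoys.  Half the compounds
    additionally carry one extra decoy (from a disjoint decoy pair) at the
    second free position.  The fixed slots keep the structural pattern
    space small enough that the planted rule is recoverable by
    nearest-neighbor similarity, while still exercising several fragments
    and connection points per class.  Observed activity is the rule XOR
    Bernoulli(noise).  Deterministic for a given (spec, n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    decoys = [f for f in spec.fragment_pool if f != spec.active_fragment]
    slot_decoys = decoys[:2]
    extra_decoys = decoys[2:4] if len(decoys) >= 4 else decoys
    records = []
    per_class_counter = {cid: 0 for cid, _ in spec.classes}
    for i in range(n):
        cid, base = spec.classes[i % len(spec.classes)]
        rule_active = per_class_counter[cid] % 2 == 0
        per_class_counter[cid] += 1
        slots = free_positions(base)
        frags = [spec.active_fragment if rule_active else
                 slot_decoys[int(rng.integers(len(slot_decoys)))]]
        positions = [slots[0]]
        if rng.random() < 0.5 and len(slots) > 1:
            frags.append(extra_decoys[int(rng.integers(len(extra_decoys)))])
            positions.append(slots[1])
        smiles = decorate(base, frags, positions)
        flip = rng.random() < spec.noise_rate
        active = rule_active != flip
        records.append(CompoundRecord(
            id=f"toy-{i:04d}",
            mol=parse_structure(smiles, "smiles", record_id=f"toy-{i:04d}"),
            class_label=cid,
            activity="active" if active else "inactive",
        ))
    return records


def write_truth(spec: ToySpec, records: Sequence[CompoundRecord],
                path) -> None:
    payload = {
        "spec": spec.as_dict(),
        "records": [{"id": r.id, "class": r.class_label,
                     "activity": r.activity,
                     "smiles": canonical_form(r.mol)} for r in records],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
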