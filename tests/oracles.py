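"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own matching and pruning code:
subgraph matching is done with networkx monomorphism search on attributed
graphs, and the scaffold hierarchy with set-level graph surgery (2-core
peeling plus the double-bond re-add rule), materialized through RDKit only
for canonical naming.
"""

from __future__ import annotations

import networkx as nx
from rdkit import Chem

from ncmfp.chem import canonical_form


def mol_graph(mol: Chem.Mol, heavy_only: bool = True) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        if heavy_only and atom.GetAtomicNum() == 1:
            continue
        g.add_node(atom.GetIdx(), element=atom.GetAtomicNum(),
                   aromatic=atom.GetIsAromatic(),
                   charge=atom.GetFormalCharge())
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in g and j in g:
            order = 1.5 if bond.GetIsAromatic() else bond.GetBondTypeAsDouble()
            g.add_edge(i, j, order=order)
    return g


def brute_force_embeddings(pattern: Chem.Mol, target: Chem.Mol) -> list[dict]:
    """All subgraph monomorphisms of pattern into target (heavy atoms),
    element/charge/aromaticity exact, bond order exact (aromatic = 1.5)."""
    gp, gt = mol_graph(pattern), mol_graph(target)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        gt, gp,
        node_match=lambda a, b: (a["element"] == b["element"]
                                 and a["aromatic"] == b["aromatic"]
                                 and a["charge"] == b["charge"]),
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    # networkx yields target->pattern dicts; invert to pattern->target
    return [{pv: tv for tv, pv in m.items()}
            for m in matcher.subgraph_monomorphisms_iter()]


def _two_core(g: nx.Graph) -> set:
    """Iteratively peel degree-<=1 nodes: leaves rings and inter-ring
    linkers."""
    h = g.copy()
    while True:
        leaves = [n for n in h if h.degree(n) <= 1]
        if not leaves:
            return set(h.nodes)
        h.remove_nodes_from(leaves)


def _framework_atoms(mol: Chem.Mol, atoms: set) -> set:
    """Framework of the induced subgraph: 2-core plus atoms double-bonded
    to a kept atom (the exocyclic/terminal double-bond rule)."""
    g = mol_graph(mol).subgraph(atoms).copy()
    keep = _two_core(g)
    if not keep:
        return set()
    for i, j, data in g.edges(data=True):
        if data["order"] == 2.0:
            if i in keep and j not in keep:
                keep.add(j)
            elif j in keep and i not in keep:
                keep.add(i)
    return keep


def _atoms_to_smiles(mol: Chem.Mol, atoms: set) -> str | None:
    """Canonical form of the fragment induced on an atom set, or None if
    it is not a chemically valid standalone molecule.

    Tried on the aromatic form first (intact aromatic rings stay
    aromatic); remnants with broken aromatic rings are materialized from
    a kekulized copy instead, and discarded if still unparseable.
    """
    candidates = [mol]
    kek = Chem.Mol(mol)
    try:
        Chem.Kekulize(kek, clearAromaticFlags=True)
        candidates.append(kek)
    except Chem.KekulizeException:
        pass
    for source in candidates:
        smi = Chem.MolFragmentToSmiles(source, atomsToUse=sorted(atoms),
                                       canonical=True)
        frag = Chem.MolFromSmiles(smi)
        if frag is not None:
            return canonical_form(frag)
    return None


def _cycle_count(g: nx.Graph) -> int:
    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)


def brute_force_levels(mol: Chem.Mol) -> dict[int, set[str]]:
    """Exhaustive pruning hierarchy by atom-set surgery.

    From the framework atom set, repeatedly delete the exclusive atoms of
    one basis ring, re-extract the framework of what remains, and keep
    results that are connected, valid and exactly one ring smaller.
    Levels are keyed by cycle count - 1; values are canonical forms.
    """
    g_full = mol_graph(mol)
    root = frozenset(_framework_atoms(mol, set(g_full.nodes)))
    levels: dict[int, set[str]] = {}
    seen_sets: set[frozenset] = set()

    def visit(atoms: frozenset):
        if atoms in seen_sets:
            return
        seen_sets.add(atoms)
        sub = g_full.subgraph(atoms)
        n_rings = _cycle_count(sub)
        smi = _atoms_to_smiles(mol, set(atoms))
        if smi is not None:
            levels.setdefault(n_rings - 1, set()).add(smi)
        if n_rings <= 1:
            return
        rings = nx.minimum_cycle_basis(sub)
        for i, ring in enumerate(rings):
            others = set().union(*(set(r) for j, r in enumerate(rings)
                                   if j != i))
            exclusive = set(ring) - others
            if not exclusive:
                continue
            remaining = set(atoms) - exclusive
            cleaned = _framework_atoms(mol, remaining)
            if not cleaned:
                continue
            sub2 = g_full.subgraph(cleaned)
            if nx.number_connected_components(sub2) != 1:
                continue
            if _cycle_count(sub2) != n_rings - 1:
                continue
            if _atoms_to_smiles(mol, cleaned) is None:
                continue
            visit(frozenset(cleaned))

    visit(root)
    return levels
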