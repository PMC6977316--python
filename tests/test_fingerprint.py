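"""Feature-dictionary construction and the six-step fingerprint engine."""

import numpy as np
import pytest
from rdkit import Chem

from ncmfp.chem import parse_structure, preprocess
from ncmfp.fingerprint import (FeatureDictionary, build_feature_dictionary,
                               compute_ncmfp, generate_fragments,
                               identify_fragment, match_scaffolds)
from ncmfp.scaffold import NoScaffoldError

from .conftest import prepared


class TestBuildFeatureDictionary:
    def test_toy_dictionary_layout(self, toy_dictionary):
        """benzene library + {toluene, phenol} reference -> 1 scaffold,
        1 connection point, 2 fragments, 4 bits total."""
        assert toy_dictionary.block_sizes == (1, 1, 2)
        assert toy_dictionary.n_bits == 4

    def test_fragments_indexed_by_ascending_weight(self, toy_dictionary):
        methyl, hydroxyl = toy_dictionary.fragments
        assert methyl.smiles == "*C" and hydroxyl.smiles == "*O"
        assert methyl.mw == pytest.approx(15.03, abs=0.01)
        assert hydroxyl.mw == pytest.approx(17.01, abs=0.01)
        assert (methyl.index, hydroxyl.index) == (1, 2)

    def test_empty_reference_scaffold_block_only(self, toy_benchmark):
        lib = toy_benchmark["library"]
        d = build_feature_dictionary(lib, [])
        assert d.n_bits == len(lib.all_scaffolds())

    def test_deterministic_given_inputs(self, toy_benchmark):
        lib, records = toy_benchmark["library"], toy_benchmark["records"]
        d1 = build_feature_dictionary(lib, records)
        d2 = build_feature_dictionary(lib, records)
        assert d1.checksum() == d2.checksum()

    def test_json_round_trip(self, toy_dictionary, tmp_path):
        path = tmp_path / "dict.json"
        toy_dictionary.to_json(path)
        back = FeatureDictionary.from_json(path)
        assert back.checksum() == toy_dictionary.checksum()
        assert back.n_bits == toy_dictionary.n_bits
        fp = compute_ncmfp(prepared("Cc1ccccc1"), back)
        assert fp.to_bitstring() == "1110"


class TestMatchScaffolds:
    def test_identity_query(self, toy_dictionary):
        matches = match_scaffolds(prepared("c1ccccc1"), toy_dictionary)
        assert len(matches) == 1
        assert matches[0].scaffold.smiles == "c1ccccc1"
        assert matches[0].sfcp_positions == ()

    def test_toluene_matches_benzene(self, toy_dictionary):
        matches = match_scaffolds(prepared("Cc1ccccc1"), toy_dictionary)
        assert [m.scaffold.smiles for m in matches] == ["c1ccccc1"]
        assert matches[0].sfcp_positions == (0,)

    def test_aliphatic_query_no_match(self, toy_dictionary):
        assert match_scaffolds(prepared("C1CCCCC1"), toy_dictionary) == []

    def test_acyclic_query_rejected(self, toy_dictionary):
        with pytest.raises(NoScaffoldError):
            match_scaffolds(prepared("CCO"), toy_dictionary)


class TestGenerateFragments:
    def test_toluene_methyl(self, toy_dictionary):
        q = prepared("Cc1ccccc1")
        (match,) = match_scaffolds(q, toy_dictionary)
        (frag,) = generate_fragments(q, match.mapping)
        assert frag.smiles == "*C"
        assert frag.mw == pytest.approx(15.03, abs=0.01)
        assert frag.count == 1

    def test_scaffold_equals_molecule_no_fragments(self, toy_dictionary):
        q = prepared("c1ccccc1")
        (match,) = match_scaffolds(q, toy_dictionary)
        assert generate_fragments(q, match.mapping) == []

    def test_mxylene_duplicate_fragments_collapse(self, toy_dictionary):
        q = prepared("Cc1cccc(C)c1")
        (match,) = match_scaffolds(q, toy_dictionary)
        (frag,) = generate_fragments(q, match.mapping)
        assert frag.smiles == "*C" and frag.count == 2
        assert len(frag.attach_atoms) == 2

    def test_fragments_sorted_by_weight(self, toy_dictionary):
        q = prepared("CCc1ccccc1O")  # ethyl + hydroxyl on benzene
        (match,) = match_scaffolds(q, toy_dictionary)
        frags = generate_fragments(q, match.mapping)
        assert [f.smiles for f in frags] == ["*O", "*CC"]
        assert frags[0].mw < frags[1].mw

    def test_single_attachment_single_marker(self, toy_dictionary):
        q = prepared("CCc1ccccc1")
        (match,) = match_scaffolds(q, toy_dictionary)
        (frag,) = generate_fragments(q, match.mapping)
        assert frag.smiles.count("*") == 1


class TestSFCP:
    def test_toluene_symmetry_reduced_to_zero(self, toy_dictionary):
        """All benzene atoms are automorphism-equivalent, so the single
        attachment reduces to canonical position 0."""
        (match,) = match_scaffolds(prepared("Cc1ccccc1"), toy_dictionary)
        assert match.sfcp_positions == (0,)

    def test_mxylene_minimal_pair_distinct(self, toy_dictionary):
        (match,) = match_scaffolds(prepared("Cc1cccc(C)c1"), toy_dictionary)
        a, b = match.sfcp_positions
        assert a == 0 and a != b and 0 <= b <= 5

    def test_positions_query_independent(self, toy_dictionary):
        """Same substitution pattern, different input atom ordering, same
        connection points."""
        mol = parse_structure("Cc1cccc(C)c1")
        rng = np.random.default_rng(3)
        seen = set()
        for _ in range(20):
            perm = rng.permutation(mol.GetNumAtoms()).tolist()
            q = preprocess(Chem.RenumberAtoms(mol, perm))
            (match,) = match_scaffolds(q, toy_dictionary)
            seen.add(match.sfcp_positions)
        assert len(seen) == 1


class TestIdentifyFragment:
    def test_known_fragment(self, toy_dictionary):
        assert identify_fragment("*C", toy_dictionary) == 1
        assert identify_fragment("*O", toy_dictionary) == 2

    def test_unknown_fragment(self, toy_dictionary):
        assert identify_fragment("*CC", toy_dictionary) is None

    def test_empty_fragment_block(self, toy_benchmark):
        d = build_feature_dictionary(toy_benchmark["library"], [])
        assert identify_fragment("*C", d) is None


class TestComputeFingerprint:
    @pytest.mark.parametrize("smiles,expected", [
        ("c1ccccc1", "1000"),
        ("Cc1ccccc1", "1110"),
        ("Oc1ccccc1", "1101"),
    ])
    def test_worked_examples(self, toy_dictionary, smiles, expected):
        fp = compute_ncmfp(prepared(smiles), toy_dictionary)
        assert fp.to_bitstring() == expected

    def test_no_scaffold_match_all_zero(self, toy_dictionary):
        fp = compute_ncmfp(prepared("C1CCCCC1"), toy_dictionary)
        assert fp.no_scaffold_match
        assert fp.to_bitstring() == "0000"

    def test_unknown_fragment_counted_not_grown(self, toy_dictionary):
        fp = compute_ncmfp(prepared("CCc1ccccc1"), toy_dictionary)
        assert fp.n_bits == 4
        assert fp.unknown_fragments == 1
        assert fp.to_bitstring() == "1100"  # scaffold + SFCP@0, ethyl unknown

    def test_acyclic_query_rejected(self, toy_dictionary):
        with pytest.raises(NoScaffoldError):
            compute_ncmfp(prepared("CCCC"), toy_dictionary)

    def test_bit_accounting(self, toy_benchmark):
        """Set-bit count = matched scaffolds + identified connection points
        + identified fragments, from per-bit provenance."""
        d = toy_benchmark["dictionary"]
        for rec in toy_benchmark["records"][:40]:
            fp = compute_ncmfp(preprocess(rec.mol), d)
            kinds = [kind for kind, _ in fp.provenance.values()]
            assert len(fp.set_positions) == len(kinds)
            assert len(fp.set_positions) == (
                kinds.count("scaffold") + kinds.count("sfcp")
                + kinds.count("fragment"))

    def test_atom_order_invariance(self, toy_dictionary):
        rng = np.random.default_rng(11)
        for smiles in ["Cc1ccccc1", "Oc1ccccc1", "Cc1cccc(C)c1"]:
            mol = parse_structure(smiles)
            ref = compute_ncmfp(preprocess(mol), toy_dictionary).to_bitstring()
            for _ in range(25):
                perm = rng.permutation(mol.GetNumAtoms()).tolist()
                fp = compute_ncmfp(preprocess(Chem.RenumberAtoms(mol, perm)),
                                   toy_dictionary)
                assert fp.to_bitstring() == ref

    def test_dictionary_scaffold_query_sets_only_scaffold_bits(
            self, toy_benchmark):
        d = toy_benchmark["dictionary"]
        for pos, scaffold in enumerate(d.scaffolds):
            fp = compute_ncmfp(prepared(scaffold.smiles), d)
            assert pos in fp.set_positions
            kinds = {kind for kind, _ in fp.provenance.values()}
            assert kinds == {"scaffold"}

    def test_constant_length(self, toy_benchmark):
        lengths = {fp.n_bits for _, fp in toy_benchmark["fps"]}
        assert lengths == {toy_benchmark["dictionary"].n_bits}

    def test_single_scaffold_mode_subset_of_multi(self, toy_benchmark):
        d = toy_benchmark["dictionary"]
        q = preprocess(toy_benchmark["records"][0].mol)
        multi = compute_ncmfp(q, d, multi_scaffold=True)
        single = compute_ncmfp(q, d, multi_scaffold=False)
        assert set(single.set_positions) <= set(multi.set_positions)
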