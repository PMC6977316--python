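"""Shared fixtures: toy feature dictionary, fixture molecule panel, and a
synthetic benchmark dataset built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from ncmfp.chem import CompoundRecord, parse_structure, preprocess
from ncmfp.fingerprint import build_feature_dictionary, fingerprint_compounds
from ncmfp.scaffold import build_library
from ncmfp.synthetic import generate_dataset, make_toy_spec

# Ringed molecules with <= 4 SSSR rings used for hierarchy / matching
# oracle comparisons.  Chosen to cover fused, linked, spiro and
# heteroaromatic systems plus exocyclic double bonds.
FIXTURE_SMILES = [
    "c1ccccc1",                     # benzene
    "Cc1ccccc1",                    # toluene
    "Oc1ccccc1",                    # phenol
    "O=C1CCCCC1",                   # cyclohexanone (exocyclic =O)
    "c1ccc2ccccc2c1",               # naphthalene (fused)
    "c1ccc(-c2ccccc2)cc1",          # biphenyl (linked)
    "c1ccc(Cc2ccccc2)cc1",          # diphenylmethane (one-atom linker)
    "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1",  # p-terphenyl (3 rings)
    "c1ccc2[nH]ccc2c1",             # indole (hetero fused)
    "c1ccc2c(c1)CCCC2",             # tetralin (aromatic/aliphatic fused)
    "c1ccc2ncccc2c1",               # quinoline
    "C1CCC2(CC1)CCCCC2",            # spiro[5.5]undecane
    "c1ccc2c(c1)Cc1ccccc12",        # fluorene (3 rings, CH2 bridge)
    "c1ccc2c(c1)[nH]c1ccccc12",     # carbazole
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",   # caffeine (exocyclic =O on ring)
    "O=c1ccoc2ccccc12",             # chromone
    "C1CCc2ccccc2C1Cc1ccccc1",      # benzyl tetralin (3 rings, branch)
]


@pytest.fixture(scope="session")
def fixture_mols():
    return {smi: Chem.MolFromSmiles(smi) for smi in FIXTURE_SMILES}


@pytest.fixture(scope="session")
def toy_dictionary():
    """The 4-bit worked example: a benzene scaffold library with toluene
    and phenol as the reference set -> 1 scaffold + 1 connection point +
    2 fragments (methyl before hydroxyl by weight)."""
    records = [
        CompoundRecord("toluene", parse_structure("Cc1ccccc1"),
                       class_label="A"),
        CompoundRecord("phenol", parse_structure("Oc1ccccc1"),
                       class_label="A"),
    ]
    lib = build_library(records, levels=[0])
    return build_feature_dictionary(lib, records)


@pytest.fixture(scope="session")
def toy_benchmark():
    """Noiseless planted-rule dataset (3 classes, n=200, seed=1) with its
    fingerprints, labels and generating spec."""
    spec = make_toy_spec(3, seed=1)
    records = generate_dataset(spec, 200)
    lib = build_library(records, levels=[0])
    dictionary = build_feature_dictionary(lib, records)
    fps = fingerprint_compounds(records, dictionary)
    bits = np.vstack([fp.bits for _, fp in fps])
    labels = np.array([r.activity for r in records])
    return {"spec": spec, "records": records, "library": lib,
            "dictionary": dictionary, "fps": fps, "bits": bits,
            "labels": labels}


def prepared(smiles: str):
    return preprocess(parse_structure(smiles))
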