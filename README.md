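# ncmfp

Scaffold-based hierarchical molecular fingerprints for natural compounds,
with the machinery around them: scaffold-library construction from
class-labeled compound sets, library diagnostics (database coverage and
class-assignment heat maps), and a Tanimoto 1-NN benchmark protocol with
Y-randomization.

## Who this is for

Natural compounds (NCs) occupy a different chemical space from synthetic
screening compounds — more oxygen, fewer nitrogens, large fused ring
systems — and general-purpose substructure-key fingerprints (MACCS,
PubChem FP) describe them poorly.  This package implements a fingerprint
whose features are derived from NC chemistry itself: it is aimed at
cheminformaticians doing natural-product virtual screening or
structure–activity modelling who need a descriptor tuned to NC scaffolds.

## The method

A compound's **Bemis–Murcko framework** keeps its rings, the linkers
between rings, and exocyclic/terminal double bonds, discarding side
chains.  Iteratively deleting one peripheral ring at a time yields a
scaffold hierarchy: a scaffold with *r* rings (SSSR) sits at **level
r − 1**, so level-0 scaffolds are single rings.  Given compounds grouped
into structural classes, the scaffolds observed per class and level form
the class scaffold libraries

    SL_i = { (s^i_{0,1}, s^i_{0,2}, …), (s^i_{1,1}, …), (s^i_{2,1}, …), … }

where `s^i_{j,k}` is the *k*-th scaffold at level *j* of class *i*.

The fingerprint of a query compound with at least one ring is a
fixed-length bit string over three ordered feature blocks:

1. **Scaffolds** — one bit per library scaffold contained in the query
   (aromatic-strict substructure matching);
2. **SFCPs** (scaffold–fragment connection points) — one bit per scaffold
   atom position at which a fragment is attached, reported on the
   scaffold's own canonical atom numbering and reduced over scaffold
   automorphisms so the bits are independent of input atom order;
3. **Fragments** — one bit per distinct fragment left when the matched
   scaffold atoms are deleted, identified by canonical SMILES (with an
   attachment marker) and indexed by ascending molecular weight.

Generation runs in six steps: hydrogen completion and index assignment;
scaffold matching; fragment generation; connection-point assignment;
fragment identification; bit-string emission.  Features observed on a
query but absent from the dictionary are dropped and counted, keeping the
vector length fixed.

Which levels to keep is informed by two diagnostics: **DB coverage**
`X^m_Y = Σ_i n^{m,i}_matched / n_Y` (fraction of database Y matched by
level-*m* scaffolds, each compound counted in one class) and the
**class-assignment heat map** `P^m_{i,j} = n^m_{i→j} / n^o_i` (fraction of
class-*i* compounds whose level-*m* scaffolds assign them to class *j*;
the ideal is the identity matrix).  Coverage falls and assignment accuracy
rises with level; levels 1–2 are the default compromise.

Benchmarking uses 1-nearest-neighbor classification under the Tanimoto
coefficient `|a ∧ b| / |a ∨ b|`, evaluated by ten seeded, stratified 80/20
splits with tenfold cross-validation on the training portion; the headline
numbers are averaged external-validation accuracy, F1 and Matthews
correlation (MCC).  Activity labels come from IC50 < 10 µmol.
Y-randomization reruns the protocol on label-shuffled copies and reports
`Z = (metric_ori − mean_rand) / sd_rand`; Z > 3 marks a significant model.

## Worked example

```python
from ncmfp import (CompoundRecord, parse_structure, preprocess,
                   build_library, build_feature_dictionary,
                   compute_ncmfp, tanimoto)

records = [
    CompoundRecord("toluene", parse_structure("Cc1ccccc1"), class_label="A"),
    CompoundRecord("phenol",  parse_structure("Oc1ccccc1"), class_label="A"),
]
lib = build_library(records, levels=[0])           # one scaffold: benzene
dictionary = build_feature_dictionary(lib, records)
print(dictionary.block_sizes)                      # (1, 1, 2)

for smi in ["c1ccccc1", "Cc1ccccc1", "Oc1ccccc1"]:
    fp = compute_ncmfp(preprocess(parse_structure(smi)), dictionary)
    print(smi, fp.to_bitstring())
```

prints

```
(1, 1, 2)
c1ccccc1 1000
Cc1ccccc1 1110
Oc1ccccc1 1101
```

The dictionary has 4 bits: the benzene scaffold, one connection point
(every benzene position is symmetry-equivalent, so both the methyl of
toluene and the hydroxyl of phenol attach at canonical position 0), and
two fragments — methyl (`*C`, 15.03 Da, index 1) before hydroxyl (`*O`,
17.01 Da, index 2).  Benzene sets only its scaffold bit; toluene adds the
connection point and the methyl bit; phenol the connection point and the
hydroxyl bit.  Their similarity is `tanimoto(fp_toluene.bits,
fp_phenol.bits) == 0.5` — two shared bits (scaffold, connection point) out
of four set in the union.

The same flow scales to real data through the CLI:

```sh
ncmfp simulate --classes 3 --n 200 --seed 1 --out toy/
ncmfp build-library --input toy/compounds.tsv --levels 0 --out library.json
ncmfp build-dict --library library.json --ref toy/compounds.tsv --out dict.json
ncmfp fingerprint --dict dict.json --input toy/compounds.tsv --out fps.tsv
ncmfp benchmark --fps fps.tsv --labels toy/labels.tsv --repeats 10 --seed 1 \
    --yrand 50 --out report.json
```

`ncmfp benchmark` accepts fingerprint TSVs from any generator, so external
bit strings (MACCS, PubChem FP, …) can be compared under the identical
protocol.

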