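# Methods

## Model and assumptions

The fingerprint treats a molecule as (scaffold, attachment positions,
fragments).  Three assumptions follow:

- **Ring requirement.** Level-0 scaffolds are single rings, so the
  fingerprint is defined only for compounds with at least one ring;
  readers exclude acyclic records (counted and logged), and fingerprint
  entry points raise on ring-free queries.
- **2D identity.** Canonical identity is the canonical SMILES of the
  heavy-atom graph: stereochemistry is parsed but ignored, and hydrogens
  are folded back in.  Two stereoisomers share a fingerprint.
- **Aromatic-strict matching.** Aromaticity is perceived at parse time and
  substructure matching distinguishes aromatic from aliphatic rings —
  benzene never matches cyclohexane.  Coverage and assignment diagnostics
  would be meaningless otherwise.

## Scaffold hierarchy

The Bemis–Murcko framework (rings + inter-ring linkers + atoms
double-bonded to them) is extracted with RDKit's Murcko scaffold routine,
which implements exactly this rule.  Pruning enumerates **all**
one-ring-removal parents, not a single canonical chain: for each SSSR
ring, the atoms exclusive to it are deleted together with any non-ring
substituent that would be stranded (e.g. an exocyclic `=O` on the removed
ring), dangling linkers are cleaned up by re-extracting the framework, and
the result is kept when it is connected, sanitizable and exactly one ring
smaller.  Level = SSSR ring count − 1; bridged and spiro systems follow
SSSR counting, and a fully-shared (bridging) ring is simply not removable.

Two numerical subtleties:

- **Re-aromatization.** Atom deletion is attempted on the aromatic form
  first, so an intact remaining ring (naphthalene → benzene) keeps its
  aromaticity regardless of kekulization; only remnants with broken
  aromatic rings fall back to a kekulized copy (tetralin's aromatic ring
  removal leaves a kekulized six-ring).  Removals that are invalid either
  way are discarded.
- **Parent–child containment.** Because a deletion can de-aromatize the
  remnant, a child need not be an aromatic-strict substructure of its
  parent; the hierarchy invariant holds (and is tested) on the element
  skeleton.

Library ordering is lexicographic on canonical SMILES within each
(class, level), making scaffold indices reproducible.  Cross-class
duplicates are retained: per-level totals are row sums over classes.

## Fingerprint generation

- **Multi-scaffold bits.** Every dictionary scaffold contained in the
  query sets its bit, and connection points / fragments are derived from
  every match site; a `multi_scaffold=False` mode restricts to the largest
  matched scaffold (most rings, then most atoms, then library order) for
  comparison.
- **Symmetry reduction.** Connection points are positions on the
  scaffold's own canonical atom numbering.  Among all
  automorphism-equivalent embeddings onto the same query atoms, the one
  minimizing the sorted position tuple is used, so symmetric scaffolds
  (all benzene positions are equivalent) give deterministic,
  query-independent bits.
- **Attachment markers.** Each cut bond leaves a dummy atom (`*`) on the
  fragment, distinguishing e.g. methoxy (`*OC`) from hydroxymethyl
  (`*CO`); the marker is massless, so fragment weights exclude it.
  A fragment attached to the scaffold at two points carries two markers —
  rare (ring remnants such as tetralin's aliphatic arc) but represented
  faithfully rather than split.
- **Fixed length.** Fragments or connection points seen on a query but
  absent from the dictionary are dropped and counted
  (`unknown_fragments`, `unknown_sfcps`); the vector never grows.
- **Weights** use average atomic masses rounded to 2 decimals for
  ordering; fragment index ties break on canonical SMILES.

The published instance of this fingerprint family is a 10,016-bit layout
over 676 scaffolds; reproducing it requires the original reference
compound set, which is not redistributable, so the dictionary builder is
the supported way to derive a layout from any class-labeled collection.

## Library diagnostics

Coverage counts each compound in **one** class: among matching classes,
the one whose matched scaffold has the largest ring count wins, ties
broken by library class order (deterministic, favors specific matches).
The heat map by default **multi-assigns** — a compound contributes to
every class whose scaffolds match it, so rows need not sum to 1 and the
matrix is generally asymmetric; `dedup=True` switches to the coverage
rule.  The two diagnostics intentionally count differently.

## Benchmark protocol

- Stratified 80/20 splits (stratification avoids empty-class test sets in
  small datasets and can be disabled), ten repeats, seeded; repeat *r*
  uses `seed + r`.
- 1-NN has no hyperparameters, so the tenfold CV on the training portion
  is reported for protocol fidelity; the averaged external metrics are the
  headline output.
- Tanimoto of two all-zero vectors (possible when nothing matches) is 0;
  1-NN ties resolve to the earliest training item (stable order,
  seed-independent) and are logged.
- Undefined 0/0 metric ratios return 0 and are flagged.
- Y-randomization defaults to 100 rounds (configurable; the analyses here
  use 20–50, which resolve Z comfortably on both sides of 3); each round
  reruns the split protocol on a label permutation.  Zero spread across
  rounds flags the result as degenerate instead of dividing by zero.
- Positive class: `"active"` when present, else the first label in sorted
  order.

## Synthetic data

The generator emulates a class-structured natural-compound collection at
toy scale: each class is a distinct single-ring system from a built-in
catalog (benzene, pyridine, thiophene, furan, pyrimidine, pyrazine,
thiazole, cyclohexane, piperidine, oxane), decorated with small marker
fragments.  Single-ring bases make the level-0 library round-trip exact.
Every compound carries either the designated "active" fragment or a slot
decoy at the ring's first free position, and half carry one extra decoy
at the second position; the planted rule (presence of the active
fragment) is therefore decidable from the structure alone and — because
the pattern space stays small relative to the sample — recoverable by
nearest-neighbor similarity.  Observed labels are the rule XOR
Bernoulli(noise).  All randomness flows from the single spec seed.

What this does **not** emulate: real NC property distributions, fused
multi-ring class scaffolds, uneven class sizes, or activity rules
involving multiple interacting substituents.  Passing tests demonstrate
the pipeline's correctness and the protocol's statistical behavior, not
performance on real natural-product data.

Default study conditions used by the tests and the acceptance script:
3 classes, n = 200, noise 0 (plus a noise-0.5 null control), ten 80/20
repeats; Y-randomization with a lighter protocol (3 repeats, no CV)
and 20–30 rounds, which keeps the whole analysis in seconds while the
Z-scores remain unambiguous.

## Known limitations

- Scaffold matching is embedding-enumeration based; pathological
  highly-symmetric queries could produce many embeddings (capped at
  100,000 per scaffold).
- SSSR ring perception can differ from other toolkits' in bridged
  polycyclics, shifting level assignment for such scaffolds.
- The coverage dedup rule is one reasonable determinization of
  "counted in one class only"; other rules (e.g. first match) would shift
  per-class counts, not the total.
- Fragment weights use average masses, so isotopically labeled inputs
  collapse onto their unlabeled forms.
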