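# Methods

## Residues and peptides

A residue is stored as a complete monomer graph parsed from SMILES, with
the two backbone attachment points marked by dummy atoms: `[*:1]` on the
nitrogen side and `[*:2]` on the carbonyl-carbon side. Full monomers (not
side chains) are kept because non-natural residues may modify the backbone
vicinity. Peptides are linear, written N→C, with no stereochemistry,
protonation states, cyclization or disulfides — the descriptor is strictly
2D and topological.

For assembly (needed only by the atom-pair baseline) monomers are joined
N→C by single bonds between each carbonyl carbon and the next backbone
nitrogen, and the termini are capped neutrally: the N-side dummy is removed
(free amine) and the C-side dummy becomes a hydroxyl oxygen (free acid).

Residue-level pattern matching deliberately runs on the monomer **with its
dummies in place**, i.e. the residue in its in-chain context. Matching the
free amino acid instead would give every residue a carboxylic acid,
hydroxyl and extra N–H, which floods exactly the patterns that should
discriminate side chains (those columns all collapsed to constant bits).
Dummy atoms match no element query and are terminal, so they cannot act as
linkers inside relational patterns.

## The vocabulary

The shipped base set has |Z| = 49 patterns in three categories:

* **atom counts** (9): the classes Cl, F, N, O, C, aromatic C, S,
  aromatic N, and "all other heavy atoms", binarized as *count ≥ t*.
  Thresholds above 1 (N ≥ 2, O ≥ 2, C ≥ 5) discount the atoms every
  backbone contributes, so the bits reflect side chains. Threshold bits
  were chosen over exact counts or bins because the descriptor is
  bit-valued and monotone thresholds preserve graded size information
  under Tanimoto.
* **substructures** (28): SMARTS presence patterns for the common
  pharmacophoric and hydrophobic groups of amino-acid chemistry
  (hydroxyl, carboxylic acid, amide, amines, guanidine, imidazole, indole,
  phenyl, thiol/thioether, methyl/methylene chains, halogens, ring
  membership, …).
* **properties** (12): relational SMARTS joining two chemotypes through
  one or two linker atoms of any kind, e.g. "a methylene and a
  hydrogen-bond acceptor connected via any atom".

This set is a documented reconstruction: the file format (`YAML`, one
entry per base pattern) makes any alternative base set loadable in its
place. Complements are always derived, never listed.

### Screening

Two statistical conditions are applied over a residue library (the
screening population is the library, not the peptide dataset):

1. **Entropy**: drop base patterns whose column entropy over the library
   is below `entropy_min` (default 0.08 bits ≈ 1% prevalence). Entropy is
   standard Shannon entropy, log base 2 — non-negative, maximal (1 bit) at
   50% prevalence.
2. **Redundancy**: for any surviving pair of base columns with Jaccard
   similarity ≥ `redundancy_max` (default 0.95), drop the lower-entropy
   member; on ties drop the later pattern in vocabulary order. Two all-zero
   columns count as identical (Jaccard 1). The scan is greedy in
   vocabulary order and idempotent: re-screening a screened vocabulary
   changes nothing.

Complement columns follow their bases automatically, so the screened
combined set always satisfies |X| = 2·|Z|.

## Pair features

An intermediate binding is a set of allowed residue counts strictly
between the two paired residues. The default gap set contains the exact
gaps {0}…{8} plus the ranges {0–2}, {0–4}, {0–8} (deduplicated;
`max_gap` 8 leaves headroom over the 3–6-residue span where informative
pairs typically live). Pairs are **directional** (N-side pattern first);
an `unordered` switch ORs mirror triples into canonical i ≤ j columns.
Same-residue pairs are excluded: co-occurrence within one residue belongs
to the residue-level patterns, and the minimal binding `~` already joins
two residues.

The matrix builder evaluates all triples at once per peptide: with B the
L×N per-position bit matrix, the existence of (x_i, y_k, x_j) is
OR over allowed gaps g of (Bᵀ_{:L-1-g} B_{1+g:}) > 0 — exactly the
existential double loop over positions, vectorized. Columns are stored
sparse, restricted to triples observed at least once in the dataset, in
canonical lexicographic (i, k, j) order; the full grid is ~38k triples per
gap spec at N = 98 and mostly empty or constant. A brute-force
position-pair enumeration written independently serves as the test oracle.

Per-feature activity association uses the phi (Matthews) coefficient of
the 2×2 feature/label table; undefined cases (constant feature or labels)
are reported as NaN, never as zero. The span of a triple is
max(allowed gaps) + 2 residues.

## Similarity screening

Tanimoto on binary vectors, with T(0, 0) := 0 so featureless peptides are
not maximally similar to everything. Candidates take the maximum
coefficient over the reference set (mean available); references are drawn
from actives only and never appear in the ranked list. Ties keep input
order, and the enrichment curve sweeps the threshold over the distinct
observed scores, closed at (0,0) and (1,1), with trapezoidal AUC. Under
random ordering the expected curve is the diagonal (AUC 0.5); perfect
separation gives AUC = 1 − n_active/(2·n_total).

## Atom-pair baseline

The comparator fingerprint sets one bit per (type_a, type_b, shortest-path
length) over the assembled peptide graph, path lengths 3–7 **bonds**
(configurable; the window is deliberately the classic short-range one).
Atom types combine element, aromaticity and simple donor/acceptor flags.
This is an APH-style baseline of our own construction — the published
atom-pair holographic code defines 36 specific key atoms that are not
reproduced here — and all outputs label it as such.

## Synthetic benchmark

The generator emulates the layout of published inhibitor screens: a small
active family sharing a binding motif against a larger background of
random peptides, over a large non-natural residue space.

* **Library**: the 20 natural monomers plus procedurally decorated
  variants up to `n_residues` (default 450). Decoration attaches one of 16
  fragments (halogens, methyl/ethyl, hydroxy, amino, methoxy, thiomethyl,
  trifluoromethyl, nitrile, phenyl, cyclohexyl, pyridyl, amide,
  isopropyl) to a side-chain carbon bearing a hydrogen; backbone atoms are
  excluded so every variant still assembles. Decoration is single-level —
  variants of natural monomers only — which keeps per-family variant
  counts, and hence pattern prevalences and screening outcomes, stable
  across seeds. Duplicates are removed by canonical SMILES.
* **Dataset**: sizes default to a published complement-C5a screen layout
  (116 actives / 451 negatives); lengths are uniform on 8–15 residues.
  The active family conserves its motif residues: the canonical (first in
  library order, hence natural) carriers of the two motif patterns,
  planted exactly `gap` residues apart at a random feasible position with
  probability `motif_penetrance` (default 1.0). The default motif is
  guanidine → 3 residues → imidazole, i.e. a conserved Arg/His
  pharmacophore pair. Negatives are uniform random sequences; options add
  full-motif decoys (`decoy_rate`) or composition-matched negatives
  carrying the same residue pair at a clearly wrong spacing
  (`match_composition`).

What the generator does **not** emulate: real binding chemistry, activity
values, family-wide sequence conservation beyond the single motif pair,
and realistic residue-usage frequencies. Passing benchmarks on this data
shows that the machinery recovers a planted pair relationship under
realistic dimensions — not that it predicts real inhibitor activity.

### Benchmark behaviour, measured

With no motif (penetrance 0) enrichment is calibrated: mean AUC ≈ 0.5
over 50 replicates. With full penetrance the planted triple is the
top-phi feature in ≥ 95% of replicates — the feature-level signal is
sharp, and ranking peptides by the planted column alone yields AUC ≈ 0.9.
Whole-fingerprint Tanimoto enrichment over the same data is much weaker
(AUC ≈ 0.6–0.7): a single conserved pair contributes on the order of 10³
shared bits against a ~10⁵-bit union in which complement patterns fire on
about half of all residue pairs, while the 8–15-residue length spread
dominates the score variance. This dilution is a property of whole-
fingerprint similarity on single-motif families, not of the feature
construction. The descriptor-contrast benchmark therefore plants an
aliphatic pair motif (gem-dimethyl → 3 residues → propylene chain,
conserved carriers Leu and Arg) spanning five residues ≈ 12 bonds: beyond
the atom-pair 3–7-bond window and compositionally invisible to atom
typing, so the pair descriptor consistently out-ranks the baseline
(win rate ≈ 1.0 over 20 replicates) exactly where its wider spatial scope
matters.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeded from the
  config; libraries, datasets and every CLI artifact are byte-identical
  across runs with the same seed. Output files carry version, config hash
  and seed in comment headers.
* Problem sizes in tests and the acceptance script: 450-residue library,
  567-peptide screens, 50 null / 20 signal / 20 contrast replicates,
  200 peptides for the brute-force oracle and 1000 vector pairs for the
  Tanimoto oracle.
* Degenerate inputs: empty peptide lists, empty reference sets, screens
  without both label classes, infeasible motifs and constant columns all
  raise or return NaN explicitly rather than silently producing numbers.

## Known limitations

* Linear peptides only; no stereochemistry, charge states or 3D
  conformations.
* The 49-pattern default base set is a reconstruction; results that
  depend on it are labelled accordingly and any base set can be supplied.
* Whether published pair descriptors treat pairs as ordered is not
  settled; directional is the stricter default here and a flag merges
  mirrors.
* The atom-pair baseline approximates the holographic code's spirit
  (typed short paths), not its exact 36 key atoms or count values.
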