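# Methods

This note documents the models, conventions and numerical choices behind
`loopscape`, and what the synthetic-data tests do and do not demonstrate
about real crystal structures.

## Coordinate model and numbering

Structures are held as ordered chains of ordered residues with explicit
atoms (label, element, coordinates in Å, isotropic B-factor in Å²,
occupancy, altloc). All region arithmetic uses **author residue
numbering** — the depositors' numbers, e.g. Gln300 — because loop
definitions in the literature are stated in that system; insertion codes
order alphabetically after the bare number. Alternate locations are kept
at parse time (file fidelity) and collapsed at selection time to the
highest-occupancy copy, ties broken by altloc letter, so geometric results
are deterministic. HETATM residues (ligands, waters) are parsed but
excluded from protein-geometry operations unless explicitly requested.
Reading supports PDB and mmCIF (via gemmi); writing is PDB only, and a
written file re-parses to an equal model at fixed-column precision
(coordinates to 3 decimals, B-factors to 2).

The default TsaBgl loop spans are L1 39–54, L2 175–183, L3 300–325,
L4 398–416. The published L3 description is internally inconsistent — the
span header runs to Tyr326 while the explicit count is "26 amino acids
(Gln300–Ile325)", and L1 39–54 spans 16 residues while the family
comparison says 14 — so both L3 variants are expressible
(`TSABGL_L3_HEADER` for 300–326) and the count-consistent span is the
default. The discrepancy is surfaced here rather than silently resolved.

## Superposition

`kabsch_fit` is the closed-form SVD solution for the least-squares proper
rotation; reflections are excluded by the usual determinant correction, so
mirror-image point sets retain a positive residual. Degenerate inputs
(< 3 pairs, collinear points — second singular value of the centered cloud
below 1e-8 of the first) raise errors rather than returning an arbitrary
rotation.

`refine_superposition` iterates fit → reject with defaults of 5 cycles and
a 2.0 rejection multiplier, mirroring common structural-alignment
practice. The rejection threshold is `reject_sigma ×` the **r.m.s.
residual** of the kept pairs: after an optimal fit the residual deviation
vectors have zero mean, so their standard deviation *is* the r.m.s.
distance. (Thresholding on the spread of the distance distribution instead
would discard roughly half of a clean Maxwell-distributed residual cloud
at 2σ.) Rejection cannot reduce the kept set below 3 pairs; exhausting the
pairs raises an error carrying the per-cycle trace.

Fits are Cα-only by default, since the quantities of interest (loop
displacement, core r.m.s.d.) are reported at Cα level; selections can
request any atom set. Residue pairing is strictly by author number — no
sequence alignment happens in this module, so it is only meaningful
between near-identical sequences (the family module handles the rest).

Per-loop r.m.s.d. is computed in two declared modes, because published
per-loop figures rarely state which frame was used:

- **core-frame** — superpose on the shared core (full chain minus all
  loops, or an explicit core region), then measure each loop's deviation
  in that frame. Sensitive to rigid-body loop motion.
- **loop-local** — superpose on the loop's own Cα. Sensitive only to
  internal loop deformation.

Reports always record the mode.

## Flexibility

Per-residue B is the **Cα B-factor**, not the residue mean. Normalization
is the z-score within a population; the population defaults to the chain,
because absolute B-factors are incomparable between crystals and datasets
(overall protein B can differ by nearly a factor of two between forms of
the same protein). A zero-variance population maps to all-zero z. Region
labels use mean z with a ±0.5 threshold; this is a reporting convention
with no physical content, and the threshold is exposed. Min–max scaling
was considered and rejected in favour of the z-score, which has the
partition identity (count-weighted region means sum to zero) that the
tests exploit.

## Contacts

Crystal structures at 1.5–2 Å carry no hydrogens, so the hydrogen-bond
criterion is the standard distance-only fallback: donor and acceptor heavy
atoms (any N; any O; hydroxyl oxygens OG/OG1/OH can donate; S optional)
within 3.5 Å. No angle term. Same-residue pairs are excluded always;
mainchain–mainchain pairs additionally require a sequence separation ≥ 2,
because the i/i±1 backbone geometry is covalently constrained. Pairs where
neither atom can donate (e.g. two carbonyl oxygens) are not contacts.

Hydrophobic contacts are side-chain carbon pairs of the apolar set
{Ala, Val, Leu, Ile, Met, Phe, Trp, Pro, Tyr, Cys} within 4.5 Å, with Tyr
restricted to ring carbons; one contact per residue pair at the minimum
C–C distance. Both cutoffs are conventions, exposed as parameters; contact
sets are monotone in the cutoff and invariant under rigid motion, and pairs
are stored once in canonical residue-key order so runs are byte-identical.

Published interaction lists for a specific protein are treated as
*membership* checks (the cited pairs must appear), not exhaustive set
equality: the criteria behind such lists are typically unstated software
defaults plus manual inspection.

## Conformer classification and pocket geometry

A displacement profile superposes chain B on chain A using only core
residues, then records each shared residue's Cα distance. Classification
takes the maximum displacement over a sub-region — for TsaBgl the
301–311 window where the folded/straight bimodality localizes — and
compares it to a 3 Å threshold: below is "reference-equal", above carries
the alternate label. Labels are always **relative to a named reference**
(for TsaBgl, the folded conformer); the method makes no absolute
folded/straight call. Classification is threshold-monotone by
construction.

Published inter-conformer quantities such as "the distances between Cα
atoms of Asp304 and Leu306 of the straight and folded loops" are read as
per-residue displacements between conformers — an intra-loop i,i+2 Cα
distance cannot reach 9 Å — and that is what the profile computes.

Pocket metrics: the entrance gap is the minimum heavy-atom distance
between the L2 and L3 loop residue sets; the entrance width has no
standard definition, so the metric is pluggable (explicit residue rim
pairs, or the maximum cross-set Cα–Cα distance between two rim loop sets)
and the definition used is recorded in the output. Width figures are
treated as orderings between conformers, not absolute values. Loop charge
is the formal count Asp/Glu = −1, Lys/Arg = +1, His = 0 — a deliberate
replacement for continuous surface electrostatics, which is out of scope.

## Family comparison

Loop mapping is pairwise reference → target, so a full MSA engine is
unnecessary. The aligner is Needleman–Wunsch with affine gaps
(Gotoh three-state DP; a length-k gap costs `open + (k−1)·extend`,
defaults 10/0.5 with BLOSUM62 loaded from Biopython's substitution-matrix
tables). Traceback ties break diagonal > up > left, making the alignment
deterministic. Correctness is pinned by an exhaustive-enumeration oracle
on short sequences and cross-checked against Biopython's independent
pairwise aligner on longer ones.

Reference loop spans are projected through the alignment: a target loop's
length is the number of non-gap target positions under the loop's column
interval, so insertions lengthen it and a loop landing entirely in a
target gap is flagged unmappable (length 0). Motif patterns use fixed
letters plus `x` wildcards; the conserved-position count of a pattern is
its number of fixed letters (the L4 pattern `WxxxDNxEWxxGxxxxFG` has 8
over an 18-column window). Column conservation is the fraction of the
most common non-gap residue.

## Synthetic data

The generator is the package's test instrument: it emulates exactly the
statistical structure the analysis assumes, with every planted feature
recorded as ground truth.

- **Backbone**: a loose helix with exact 3.8 Å Cα spacing (turn 50°,
  radius 3.5 Å, rise ≈ 2.39 Å). This keeps non-adjacent residues > 5 Å
  apart, so no accidental polar contacts arise and planted hydrogen bonds
  are the only ones present. Backbone N/C/O, CB and short apolar
  side-chain stubs are placed in the local frame of the **unswung**
  template, and each residue moves rigidly, so conformer twins are
  bit-identical outside the flexible span and a rigid inter-chain
  transform is exact at all atoms.
- **Defaults** are the study conditions the tests assume: 200 residues;
  four loops of 16/9/26/19 residues mirroring the TsaBgl loop lengths;
  a 6 Å swing on the L3-like loop (the observed folded↔straight
  displacement is of this order); per-axis coordinate noise 0.1 Å
  (typical coordinate uncertainty at this resolution); B-factor background
  20 ± 5 Å² with +10 Å² (+2 sd) inside the flexible span, matching the
  reported contrast between the flexible loop and the protein average.
- **Swing**: a smooth sine bump over the flexible span, scaled so its
  maximum equals the amplitude exactly, directed radially off the helix
  axis. Planted hydrogen bonds place an acceptor at exactly 2.9 Å from a
  donor, pointing away from the chain.
- **Determinism**: one seeded generator per call; identical (spec, seed)
  produce byte-identical PDB files.
- **Families**: homologs are reference copies with seeded substitutions
  (never at planted invariant columns) and mid-loop indels;
  `force_variation` guarantees every non-invariant column varies in at
  least one homolog, so "fully conserved ⇔ planted" holds exactly.

What passing on synthetic data does *not* show: real loops move along
curved, sterically constrained paths, B-factors absorb model and
refinement error, side chains have rotamers, and real sequence families
violate the independence of mutations across sites. The synthetic results
validate the *machinery* (geometry, statistics, bookkeeping), not any
biological claim; checks against the deposited TsaBgl structures exist in
the test suite and activate when the published coordinate files are
supplied locally.

## Problem sizes and tolerances

Test ensembles use 70–200-residue chains; replicate counts are 200 for the
noise law (mean unfitted r.m.s.d. within σ√3 ± 10% at σ = 0.5 Å), 50 seeds
for conformer classification and 100 for flexible-loop identification
(≥ 95% required), and the alignment oracle enumerates all pairs of length
≤ 4 over a 4-letter alphabet. Rotation-grid oracles sample 10⁵ random
rotations. Normalization identities hold to 1e-9; transform recovery to
1e-6; file round-trips to fixed-column precision. These sizes were chosen
so each property is measured well inside its stated tolerance while the
whole suite stays fast enough to run on every change.

## Known limitations

- No symmetry-mate generation, assembly expansion, or SEQRES/ATOM
  reconciliation; the asymmetric-unit content is what is analysed.
- No TLS/anisotropic B handling; B-factor z-scores inherit whatever the
  depositing refinement put into the isotropic column.
- Contact detection has no angle terms, explicit hydrogens, π-stacking or
  salt-bridge special-casing, and no energies.
- The aligner is pairwise global only; it should not be used across very
  distant homologs where loop boundaries themselves become ambiguous.
- Pocket "width" is a declared convention, not a physically unique
  quantity.
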