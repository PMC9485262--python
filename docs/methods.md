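# Methods

This note records how `amgkit` defines its computations, the defaults it
ships, and what its synthetic fixtures do and do not demonstrate.

## Genomic-context classification

A candidate AMG is judged by the annotation classes of the genes around it.
*Upstream* is every gene with a smaller index, *downstream* every gene with a
larger one; the optional `window` parameter (genes per side, default
unlimited) tightens this, since the underlying rule set does not bound the
neighbourhood. The five categories are evaluated edge-test first, then in
numeric order 0→3; because a category-0 context also satisfies category 1's
clauses, the order itself encodes decreasing confidence and makes the
negative clauses ("without hallmark") redundant. Three choices were open and
are fixed as follows:

- **Hallmark ⊂ viral-specific.** Hallmark genes count as viral-specific in
  the both-sides tests; otherwise category 1 would be unsatisfiable as
  worded.
- **Totality.** A context with no viral gene on either side of a non-edge
  candidate falls through to category 3, the weakest non-edge class. This
  keeps the classifier total without ever inflating confidence.
- **Circular contigs** have no edge; both sides wrap around and are truncated
  at the antipodal gene, which (for an even gene count) belongs to neither
  side.

The lysozyme exclusion threshold defaults to an HMM e-value of 1e-5, a
conventional profile-significance level; it is configurable because the
screening context does not fix one. Host consensus is majority vote (≥2 of
WIsH, VirHostMatcher, PHP) at a configurable rank, default phylum, with
plain strings compared verbatim when no lineage is given.

## Conservation profiling

Alignment trimming keeps everything between the first and last key column
and, outside that span, only columns whose gap fraction is strictly below
10%. Residue frequencies use sequences with a non-gap residue at the column
as denominator; the gap fraction is reported separately against the full
subset, so the all-sequences denominator can be recomputed from the output.
Group labels are a pure function of (site-1 residue, clade): C/D in Clade 1
→ Group 1.1/1.2, Clade 2 → Group 2, N/D in Clade 3 → Group 3.1/3.2,
anything else → `other`. Clade membership is supplied (from a tree or a
table), never inferred, because clades come from an externally built
phylogeny.

## Structure analysis

- **Superposition.** Kabsch SVD with the determinant correction (proper
  rotations only). Pairing defaults to identical author residue numbers —
  correct for the isomorphous apo/mutant crystals — with an explicit pairing
  map for non-isomorphous comparisons. RMSD is over the paired Cα set.
- **SASA.** Shrake–Rupley with a deterministic Fibonacci-spiral lattice,
  default 960 points/atom, probe 1.4 Å (water radius), Chothia-style radii
  (C 1.87, N 1.65, O 1.40, S 1.85 Å) with an override table. Determinism was
  preferred over speed; at 960 points the two-sphere cap benchmark is
  reproduced to ~0.3%.
- **Interface burial.** Per monomer, SASA(alone) − SASA(in complex), waters
  excluded; contact residues are those losing area or within 4 Å of the
  partner. The definition is symmetric and exact by construction.
- **Hydrogen bonds.** X-ray models usually lack hydrogens, so the default
  criterion is heavy-atom: donor–acceptor ≤ 3.5 Å and antecedent–donor–
  acceptor angle ≥ 90°, with same-residue, covalently close (<2.2 Å) and
  adjacent mainchain–mainchain pairs excluded. Ligand N/O atoms act as both
  donor and acceptor since their protonation is unknown.
- **Secondary structure.** A Kabsch–Sander-style assignment: amide H rebuilt
  along the preceding C=O, electrostatic energy threshold −0.5 kcal/mol,
  n→n+4 turn pairs → α-helix, n→n+3 → 3₁₀, bridge patterns → ladders (E) or
  isolated β-bridges (B). All polymer chains are patterned together so
  inter-chain ladders are found. Helices are numbered α1… in sequence order
  regardless of kind (the enzyme's two single-turn 3₁₀ helices are
  conventionally called α1/α2); strands β1…. On ideal fixtures the assignment
  is identical to an independent DSSP implementation (mdtraj), which the
  tests assert.
- **ψ/DPBB motifs.** A ψ-motif is matched as a strand triple: one long
  strand bent with inter-segment axis angle in [60°, 120°] (the "almost 90°"
  bend), one long strand antiparallel (≥140°) to its C-terminal half, and a
  short strand parallel (≤30°) to the same half, all mutually adjacent
  (min Cα–Cα ≤ 7 Å). A barrel is two disjoint motifs whose short strands
  form an adjacent antiparallel pair; the pseudo-twofold RMSD superposes one
  motif's Cα set onto the other's role-wise. The tolerances are deliberately
  generous because the defining geometry is qualitative.
- **Acidic cluster.** Single-linkage clustering of Asp/Glu carboxylate
  centroids at 6 Å, ranked by size then compactness — a deliberately simple
  operationalisation of "acidic residues clustering in the cleft".
- **Subsites.** Sugars are ordered from the reducing end via the C1→O4
  glycosidic bonds (free anomeric C1 marks the reducing end); the sugar
  closest to the catalytic proton-donor residue (default 157) takes subsite
  −1, with −2, −3… toward the non-reducing end and +1… toward the reducing
  end, the standard glycosidase convention. Contacts combine the H-bond
  detector with a 4 Å heavy-atom neighbourhood.
- **Charge vs pH.** Henderson–Hasselbalch mean charges from intrinsic pKa
  values (Asp 3.9, Glu 4.1, His 6.0, Cys 8.4, Tyr 10.5, Lys 10.5, Arg 12.5,
  termini 8.0/3.1). This is a deliberately simple surrogate for a
  Poisson–Boltzmann calculation: no site–site coupling, no desolvation, so
  only trends with pH (e.g. the cleft being more negative at pH 5.5 than at
  4.6) are meaningful, not absolute surface potentials.
- **Ramachandran.** Coarse rectangular contours per residue class (general /
  Gly / Pro / pre-Pro) for favored and allowed regions. Published "preferred
  region" percentages come from density-based validators; agreement with
  this coarse set is expected only to about one percentage point, which is
  the tolerance the acceptance check uses.
- **Tie-breaking** is lexicographic on (chain, residue number, atom name)
  everywhere, and alt-locs collapse to the highest-occupancy conformer
  (ties → alphabetically first alt-loc) before any geometry.

## Synthetic data

The generator produces the study's input classes with known ground truth:
contigs realizing each rule branch; alignments with planted per-column
residue distributions and gap rates (the acceptance run plants the observed
viral site-1 mixture — 77.46% D, 14.79% C, 7.75% N — at the 142-sequence
scale); ideal helices at φ/ψ = (−57°, −47°); antiparallel strand pairs at
(−139°, 135°) whose second strand is placed by a deterministic least-squares
fit pulling the narrow-pair N···O distances to 2.9 Å (so each engineered
bond clears the 3.5 Å criterion by a wide margin); two-sphere dimers whose
burial follows the spherical-cap closed form; and a strand-level double-ψ
barrel built from two ψ-motifs related by an exact twofold, whose
pseudo-twofold RMSD is zero by construction.

What the fixtures do **not** emulate: side chains beyond the specific planted
residues, crystallographic disorder, solvent networks, realistic gene
content, or sequence evolution. Passing the synthetic suite therefore
demonstrates correctness of the rules and geometry on clean inputs; accuracy
on deposited crystal structures is checked separately by the acceptance
tests that download the five V-Csn entries (7TVL–7TVP), which require
network access.

## Problem sizes

The shipped tests and the acceptance script use deliberately small,
fixed-size problems: 200-point superpositions over 100 seeds, 960-point SASA
lattices with a 40 000-point Monte-Carlo oracle on a ~52-atom coil,
8-residue strand pairs, 12-residue helices, and 142–1000-sequence
alignments. These sizes put every statistical check well inside its
tolerance (e.g. the binomial 99% CI for planted frequencies) while keeping
the full suite in the tens of seconds.

## Known limitations

- The ψ-motif detector is tuned to the qualitative geometry of DPBB folds;
  heavily distorted barrels or strands fragmented by the SS assignment may
  need the angle tolerances widened.
- The secondary-structure assignment implements the helix/strand/bridge core
  of the Kabsch–Sander scheme, not its full state machine (no π-helices,
  turns or bends); for the analyses here only H/G/E/B matter.
- Charge profiles ignore electrostatic coupling between the clustered acidic
  residues — exactly the situation where intrinsic pKa values are least
  accurate — and are therefore reported as trends only.
- The model-content counter reports both alt-loc conventions
  (`protein_atoms` and `protein_atoms_all_conformers`) because deposited
  atom counts do not state which convention they use.
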