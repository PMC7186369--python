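# Methods

This note documents the models and procedures implemented in `stralign`,
the parameters that matter, the numerical choices, and what the synthetic
test bed does and does not establish about behavior on real structures.

## Pairwise alignment model

The alignment engine is a three-state Gotoh dynamic program (match /
gap-in-first / gap-in-second) maximizing the summed pair score minus
affine gap costs. A gap run of length L costs `open + (L−1)·extend`;
terminal gaps are penalized like internal ones. The intended inputs are
full-length homologous family members, for which true global alignment is
the right model; free terminal gaps would be preferable for fragment
alignment, which is out of scope. A gap run in one sequence immediately
followed by one in the other opens a new gap. Traceback ties resolve
match > gap-in-second > gap-in-first, so output is deterministic. The same
engine runs in three regimes:

* secondary-structure strings with ScoreS ∈ {−1, 0, 1}, penalties (1, 0);
* distance-signal windows with ScoreP and penalties (0, 0) — with zero
  penalties the program reduces to free monotone matching, i.e. dynamic
  time warping;
* superposed coordinates with ScoreC = exp(−γ‖Δα‖²), penalties (1, 0.01).

γ defaults to 0.03 Å⁻², giving ScoreC ≈ 0.62 at 4 Å and ≈ 0.15 at 8 Å:
residue pairs beyond 8 Å contribute essentially nothing, pairs inside the
4 Å equivalence cutoff contribute strongly.

### Initial superposition

Three candidate transforms are generated: signal superposition with
first-residue anchors, with last-residue anchors, and secondary-structure
superposition. Windows are 30 residues with stride 1 ("overlapping" taken
maximally dense); chains shorter than 30 shrink the window to
`max(10, N//2)` so short chains remain alignable (`segment_length`
exposes this). Each candidate is scored by running the full coordinate
alignment under it; the best ScoreC sum wins, with ties (within 1e-9)
resolved signal/first > signal/last > secondary for determinism. The
winner is refined by Kabsch re-superposition on its matched pairs
followed by re-alignment; refinement repeats up to `refine_iterations`
(default 1) rounds and stops early when the score gain is ≤ 1e-6. The
reported alignment score contains no gap terms, so it is exactly the
quantity the guide tree normalizes.

The Kabsch solver uses the SVD of the cross-covariance with the usual
det-sign correction, so every returned rotation is proper (det +1) even
for degenerate point sets.

## Progressive multiple alignment

Pairwise similarities (score per aligned pair, in [0, 1]) become distances
d = 1 − s. The guide tree is built by agglomerative clustering with
complete (maximum) linkage: after a merge, the distance from the new
cluster to any other is the maximum over its members. This realizes the
requirement that tight sub-families merge before distant relatives and is
fully deterministic (ties break lexicographically on node ids). Linkage
clustering was chosen over a literal neighbor-joining variant because the
downstream consumer needs only a rooted binary merge order, which linkage
provides directly.

Each merge aligns two alignment nodes. A node is a stack of structures
collapsed to: column-averaged Cα coordinates, inherited secondary codes,
per-column aligned-residue counts, and the consensus row = counts × cw.
Before aligning, each node's consensus is multiplied by half the other
node's structure count (exact n/2, including odd n) and attached as a
fourth coordinate inside ScoreC only — the geometric steps (signal
windows, Kabsch) always operate on plain 3-D coordinates, since the
augmented dimension has no spatial meaning. After alignment the parent's
coordinates are the unweighted mean of its children at doubly occupied
columns (the stated averaging has no stack-size weights), the occupied
child's elsewhere; secondary codes come from the non-gapped child, or the
first child when both are present; counts add; the stored consensus is
recomputed as counts × cw.

With cw = 0 the feedback is off and merges are independent pairwise
alignments; with the default cw = 1 fully aligned columns in both children
carry equal consensus, score high, and resist gap insertion. The test
suite checks the directional claim (gap-less core with cw = 1 ≥ cw = 0 on
a mixed family); on families clean enough to align gap-free either way the
two settings coincide.

## Secondary structure ("DSSP-lite")

Secondary structure feeds only ScoreS, which tests code equality, so a
3-class alphabet {H, E, C} suffices and the assignment is internal rather
than delegated to an external DSSP binary. Hydrogen bonds use the
Kabsch–Sander electrostatic energy
E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol with a bond
when E < −0.5; the amide H is reconstructed 1.0 Å from N along the
previous residue's C=O direction. H covers residues spanned by two
consecutive i→i+4 turns; E marks parallel/antiparallel bridge partners
(helix wins conflicts); everything else is C, and residues with
incomplete backbones are '-'. Energies are clamped at −9.9 kcal/mol for
clashing geometries, and pairs closer than 2 in sequence are excluded.
A `sec_codes` argument on `read_pdb` accepts externally computed codes.

## Features

* **GNM** (cutoff 10 Å): Kirchhoff matrix with unit springs; square
  fluctuation of residue i is Σ_k u_{ki}²/λ_k over the
  `min(n_modes, N−1)` smallest nonzero modes, `n_modes` = 50 by default.
* **ANM** (cutoff 15 Å): standard 3N×3N Hessian with super-elements
  −(r_ij r_ijᵀ)/‖r_ij‖²; per-residue fluctuations sum the three Cartesian
  components over `min(n_modes, 3N−6)` smallest nonzero modes.
* Zero-mode identification is by expected null-space count (1 for GNM, 6
  for ANM), not a loose magnitude threshold: elongated chains have
  physical modes many orders softer than the stiffest mode yet clearly
  above machine noise, and a relative cutoff misclassifies them. If the
  (count+1)-th smallest |λ| sits below 1e-11·max|λ| the network is
  reported as degenerate/disconnected (for GNM, with the connected
  components named). With all modes both models equal the pseudo-inverse
  diagonals, which the tests assert at 1e-6 relative.
* **Backbone features**: best (most negative) Kabsch–Sander energy per
  residue as donor or acceptor; Shrake–Rupley accessibility (biotite,
  summed per residue); α = virtual dihedral CA(i−1..i+2); κ = bend angle
  at CA(i) between CA(i−2) and CA(i+2); φ/ψ; tco = cosine between the
  C=O bonds of residues i and i−1. Undefined entries (termini, missing
  atoms) are NaN.
* **Residue depth**: mean distance of a residue's atoms to a sampled
  solvent-accessible surface (spheres of radius vdW + 1.4 Å probe,
  256 Fibonacci points per atom, points inside any other expanded sphere
  discarded). Sampling directions are fixed in a canonical molecular
  frame (principal axes oriented by projection skewness), which makes the
  depth exactly rigid-motion invariant rather than invariant only up to
  sampling error. Accuracy is bounded by `sphere_points`, exposed in the
  API. Atom-level depth is reduced to Cα, Cβ (Cα for Gly) and
  residue-mean columns.

The feature matrix is structures × columns × features with NaN at gap
cells; `drop_gap_columns()` implements the usual ML preprocessing of
keeping only fully aligned positions. Note two NaN provenances: gap cells
(no residue) and undefined features (e.g. φ of the first residue);
`drop_gap_columns` removes both.

## Quality metrics

Pair metrics use one common superposition: every structure is
Kabsch-superposed onto the longest one (ties: first by id) on the
alignment's gap-less columns, then RMSD and ≤ 4 Å equivalent-residue
counts are averaged over unordered pairs. A per-pair re-superposition
mode is deliberately not the default, as the common-frame variant is what
the family-level metrics are defined on. The equivalence score counts
gap-less columns whose residue-index tuple appears as a column of the
reference alignment, as a percentage of gap-less columns; mismatched
sequences between test and reference alignments raise an error naming
the structure.

## Synthetic test bed

Structures are grown by NeRF (internal-to-Cartesian) from ideal bond
lengths/angles and block torsions: helix (−57, −47), strand (−139, 135),
type-I′ turns, and coil torsions sampled from a broad
polyproline/extended region with clash-avoidance retries (a self-avoiding
walk with the native 3.8 Å Cα step). Carbonyl O and Cβ are placed with
ideal geometry, so hydrogen bonding, torsion read-back and DSSP-lite all
behave like real backbones. Families are perturbed copies (i.i.d.
Gaussian noise per atom) under random rigid motions, emulating the
noise-seeded family construction used for scaling experiments;
`scaling_benchmark_groups` builds those families (sizes 13–93 by default)
for informational runtime measurements, which are hardware-dependent and
never asserted.

What the synthetic bed does not emulate: real side chains (accessibility
and depth see backbone + Cβ only), Ramachandran-correlated noise,
genuine evolutionary insertions (modelled as residue deletions with
unchanged survivor coordinates), or multi-chain/hetero-atom content.
Passing tests therefore establish the algorithmic contracts — optimality
of the DP, invariances, gap placement, consensus behavior, oracle
agreement — not benchmark-level accuracy on curated reference datasets,
which requires external data.

Test problem sizes (60-residue chains, families of up to 8) were chosen
so the full suite exercises every code path in seconds while remaining
large enough for the statistical checks (noise scaling within 20%,
monotonicity over 10 replicates) to be stable.

## Known limitations

* The ScoreC matrix is dense (O(nm) memory per pairwise step), fine at
  family scale (overall O(n²l²) time), not for proteome-scale search.
* DSSP-lite implements only helix/strand/coil; 3₁₀ and π helices merge
  into H or C depending on their i→i+4 bonding.
* Secondary superposition fails (by design, with an error the caller
  catches) when fewer than 3 residue pairs align, e.g. all-coil vs
  all-helix inputs; the signal strategies then carry the alignment.
* `equivalence_score` requires identical residue sets in both alignments;
  it does not attempt fuzzy sequence matching.
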