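# Methods

`coevodyn` maps candidate allosteric communication networks in a protein
family by combining two independent evidence channels on a shared reference
residue numbering: coevolution statistics computed from a curated multiple
sequence alignment (MSA), and collective-motion statistics computed from Cα
trajectories. This note records the models, estimators, parameter choices and
numerical conventions, and what the synthetic-data validation does and does
not show.

## Alignment curation

A family MSA (FASTA or Stockholm) is mapped onto a reference sequence —
typically the chain of a crystal structure — by Smith–Waterman local
alignment of every row against the reference. The curation protocol:

1. **Reference filter.** Rows below `min_identity` (default 0.95) to the
   reference are dropped. Identity is counted over the full reference length,
   so short fragments cannot pass on a partial overlap.
2. **Column truncation.** The best-matching row anchors a strictly
   increasing column → reference-residue map; columns not aligned to a
   reference residue are removed from all rows. All downstream results are
   reported in 1-based reference numbering.
3. **Redundancy filter.** A greedy pass in input order keeps a row iff its
   identity to every already-kept row is ≤ `max_identity` (default 0.99),
   with the reference row anchored first. The greedy order is part of the
   contract: the filter is deterministic and idempotent.
4. **Gap filter.** Rows with strictly more than `max_gap_frac` (default
   0.20) gaps are dropped.
5. **Weighting.** Single-linkage clustering at `cluster_identity` (default
   0.62, the convention of weighted-MI pipelines; the threshold is not
   canonical and is configurable): clusters are connected components of the
   identity ≥ threshold graph, each sequence gets weight 1/|cluster|, so
   every cluster contributes total weight 1 and Σ weights = n_clusters.

Pairwise identity is matches divided by aligned non-gap-pair columns; 'X'
(unknown) never matches and scores 0 in alignments. Smith–Waterman uses
BLOSUM62 with affine gaps (open 10, extend 0.5; a length-L gap costs
open + (L−1)·extend) through Biopython's `PairwiseAligner`; scores are
verified against an independent Gotoh dynamic-programming oracle in the test
suite. The sequence-space PCA encodes each sequence as the concatenation of
substitution-matrix score columns of its residues (gaps/X → zeros) and
decomposes the weighted, centered encoding.

## Conservation and coevolution

**Conservation** per column is the Kullback–Leibler divergence of the
gap-excluded, renormalized residue frequencies from a background distribution
(uniform by default), mapped to [0, 11] by dividing by ln 20 — the KL of a
fully conserved column against the uniform background — and clipping. 11
renders as `*` (maximally conserved), matching the familiar alignment-viewer
scale. All-gap columns are reported missing.

**Mutual information.** For columns i, j,

    MI(i,j) = Σ_ab p_ij(a,b) · ln[ p_ij(a,b) / (p_i(a) p_j(b)) ]   (nats)

with weighted pair frequencies. The low-count correction is a symmetric
pseudocount λ (default 0.05) added to every cell of the pair-count table
before normalization. Two gap conventions are provided; the default
`exclude_pairs` counts a sequence toward pair (i, j) only when it is ungapped
at both columns, which keeps the randomization null (below) exact. At λ = 0
the estimator satisfies MI(X, X) = H(X) identically.

**Background correction.** The product (APC-style) correction

    corrected(i,j) = MI(i,j) − mean_i(MI) · mean_j(MI) / mean_all(MI)

with means over off-diagonal entries, suppresses the entropic and
shared-ancestry background that inflates raw MI uniformly across a column's
pairs. Corrected values can be negative. On star-phylogeny synthetic
alignments the corrected ranking recovers planted couplings with strictly
higher average precision than raw MI (validated over seeded replicates).

**z-scores.** Each of `n_randomizations` (default 100) null alignments
permutes the amino-acid letters within every column while leaving gaps (and
'X') fixed in place — preserving both the column compositions and every
sequence's gap pattern. The statistic (corrected MI by default) is recomputed
per randomization; z(i,j) = (obs − null mean)/(null sd) with per-pair moments
(a pooled-moment variant is available). Pairs with zero null spread are
reported missing. Edges use the inclusive threshold z ≥ 6.5, the operating
point commonly quoted for MI-based contact prediction; per-residue cumulative
scores sum the positive z of incident pairs (the raw-MI variant is exposed
for comparison).

Under an independent-column null (2,000 sequences, 100 randomizations) the
empirical z distribution is centered (|mean| < 0.05), unit-scale
(sd ∈ [0.9, 1.1]), and < 1% of pairs reach 6.5.

## Trajectory analysis

Trajectories are frames × residues × 3 Cα coordinates (nm) with time step dt
(ps); velocities (nm/ps) are taken from the input or derived by central
differences. Rigid-body motion is removed by Kabsch least-squares
superposition of every centered frame onto a centered reference frame
(collinear references are rejected as degenerate).

**PCA.** The 3N×3N positional covariance C = ⟨Δx Δxᵀ⟩ (population mean over
frames) is diagonalized; eigenvalues are mean-square fluctuations sorted
descending (stable order on ties, deterministic sign: largest-magnitude
component positive), and Σλ equals trace(C) to 1e-8 by construction.
Projections of the centered trajectory onto mode k have variance λ_k; a
trajectory can be filtered along one mode (mean + that mode's motion only).

**Cosine content** of projection p over T frames,
c_i = 2(Σ cos(iπt/T) p_t)² / (T Σ p_t²), is the standard diagnostic for
random-diffusion-like sampling; converged oscillatory modes report values far
below the usual 0.005 reporting bound, pure cosines give 1.

**Anharmonicity** is negentropy J = ½ln(2πeσ̂²) − Ĥ in nats, with Ĥ a
histogram differential entropy on Freedman–Diaconis bins. J ≈ 0 for Gaussian
(harmonic, thermally sampled) modes, ½ln(2πe/12) ≈ 0.1765 for uniform
amplitudes, and large for double-well (two-state) modes. The measure is not
canonical in the literature; the histogram rule is declared here and held
fixed.

**FCA.** Full correlation analysis searches the orthogonal transforms of the
top-m PCA coordinates (default m = 10; the restriction to a small m is a
tractability choice justified by the top modes carrying the large
majority of the fluctuation) for the one minimizing the summed pairwise
mutual information of the coordinates. MI uses equal-count (quantile)
marginal bins with ⌈n^(1/3)⌉ bins per axis — the full joint entropy of the
original formulation is not estimable at this scale, but the pairwise-sum
objective has the same minimizer family for pairwise-dependent mixtures.
Minimization is by Jacobi-style pairwise rotations: for each coordinate pair
the rotation angle is scanned over [0°, 90°) (120 grid points; MI is
invariant under 90° rotations and sign flips), and a rotation is accepted
only if it lowers the total MI over all pairs it touches, which makes the
recorded per-sweep objective provably non-increasing. Sweeps stop when the
decrease falls below `tol` (default 1e-3 nats); non-convergence returns the
best transform with a warning flag. Output modes are ordered by
anharmonicity descending — a low-amplitude double-well mode outranks a
larger harmonic one — and the fraction of total fluctuation carried by the
top-2 modes is reported.

**Per-residue dynamic weights** of a unit mode are the summed squared x/y/z
components per residue (they sum to 1); the pipeline pools the top-2
anharmonic modes. The residue–residue dynamic cross-correlation map is the
3×3-block-traced, normalized covariance.

**VACF.** The normalized velocity autocorrelation
C_v(τ) = ⟨v_i(t+τ)·v_i(t)⟩/⟨v_i²⟩, averaged over atoms and time origins
(FFT-based, C_v(0) = 1), is Hann-windowed and Fourier-transformed; the
frequency axis maps to wavenumbers via 33.35641 cm⁻¹/THz. Intensity is the
transform magnitude; the grid is zero-padded 4-fold for peak localization,
and peak positions are quoted against the unpadded VACF grid resolution
1/(n·dt). A coherent oscillator reproduces cos(ωτ) to 1e-3 and peaks within
one grid bin of its planted wavenumber.

## Network analysis

Nodes are reference residue numbers carrying the cumulative MI score; edges
carry z. Communities come from deterministic greedy (CNM) modularity
maximization on edge weights (networkx); Q is reported and validated against
the direct formula Σ_c [w_in/W − (s_c/2W)²]. The 2-D layout is classical
(Torgerson) scaling of the shortest-path (hop) metric refined by SMACOF
stress majorization, implemented in-package so the per-iteration stress
history — provably non-increasing — is available; connected components are
laid out separately and packed. Linker residues have at least one edge into
a foreign community and rank by (number of foreign communities, node score).
Communication paths use edge length 1/z (stronger coevolution = shorter;
−ln(z/z_max) is available) with Dijkstra/Yen k-shortest paths.

## Fusion and ranking

The overlay flags residues at or above the `quantile_cut` (default 0.90)
quantile of the dynamic weight as "important" (quantile 1 flags none by
convention), extracts the subgraph they induce, and records community and
linker status. The combined ranking orders by (linker flag, dynamic weight ×
MI node score) descending with residue-number ties — a product, not a sum,
so a top residue must be nontrivial in both evidence channels, mirroring
how shortlists of allosterically implicated residues intersect high-MI and
high-fluctuation sets. The pipeline writes every artifact as TSV plus a JSON
manifest (parameters, seeds, input digests); re-running from the manifest is
byte-identical.

## Synthetic data: what it emulates, and what it does not

`gen_msa` draws independent columns from a background distribution, with
optional conserved columns (dominant residue with probability p), coupled
pairs (with probability ρ, column j is a fixed bijective image of column i —
chosen over a Potts sampler because the planted truth stays analytically
checkable, e.g. MI = H(X) at ρ = 1), star-phylogeny redundancy (founders
expanded into i.i.d.-mutated copies, sufficient to exercise weighting and the
shared-ancestry correction without a tree simulator), and i.i.d. gaps.
`gen_trajectory` sums planted collective modes — coherent harmonic cosines
(for spectral analytics), Gaussian/Ornstein–Uhlenbeck thermal modes (the
amplitude statistics of a harmonic well in a heat bath), and double-well
Langevin modes — on unit shape vectors plus isotropic Gaussian noise, with
analytic or finite-difference velocities and a Nyquist guard. `gen_graph`
produces weighted planted-partition graphs.

A deterministic cosine has an arcsine (bimodal) amplitude law and therefore a
*higher* negentropy than a Gaussian; the anharmonicity-ordering contracts are
accordingly validated against the thermal (Gaussian) mode kind, which is the
physically relevant comparison. The default end-to-end bundle uses a
double-well barrier of 6 (thermal units), at which the two-state mode
outranks every other planted kind.

Real families and trajectories differ from these generators in ways the
tests deliberately do not probe: true phylogenies are not star-shaped, real
coevolution is not bijective, gap patterns are structured, and protein modes
are neither perfectly harmonic nor memoryless. Passing the synthetic
validation shows the estimators recover the structure they are defined to
measure — not that any particular biological family will yield the same
networks.

## Problem sizes and determinism

The validation suite and the acceptance script use desk-scale problem sizes
chosen once: null calibration at 2,000 sequences × 30 columns with 100
randomizations; recovery sweeps at 10 seeds per condition (the
average-precision sweep intentionally uses small, gapped, skewed-background
alignments so the ranking is not saturated at 1.0); mode recovery at
2,500–5,000 frames; the end-to-end bundle at 400 sequences × 30 columns and
30 residues × 2,500 frames with 8 FCA coordinates. All randomness flows
through explicit integer seeds; fixed seeds give bit-identical results, with
floating-point reductions accumulated in fixed order.

## Known limitations

- The Smith–Waterman traceback tie-break is Biopython's deterministic choice;
  scores are optimal but the reported alignment among co-optimal ones is
  library-defined.
- Per-pair null moments at the default 100 randomizations make z-scores
  slightly heavy-tailed (sd estimated from 100 draws); the pooled-null option
  trades pair specificity for stability.
- The FCA angle grid bounds the demixing resolution at ~0.75°; histogram MI
  is biased upward at small samples, which cancels in comparisons but not in
  absolute values.
- Greedy CNM modularity can merge small communities near the resolution
  limit; the community count on real data is algorithm-dependent.
- KL conservation values above 11 (possible against non-uniform backgrounds)
  are clipped.
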