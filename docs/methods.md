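# Methods

This note records the models, statistics and numerical choices behind
`memhomology`, in the order the pipeline uses them.

## The problem setting

Membrane-protein families are compositionally constrained: residues inside
the bilayer are drawn overwhelmingly from a small hydrophobic alphabet.
Two unrelated proteins that each cross the membrane four times therefore
share far more sequence signal than two unrelated soluble proteins, and
standard alignment statistics (Karlin–Altschul E-values calibrated on
average composition) overstate significance.  Every inferential statistic
in this package is therefore paired with a null model that *keeps* the
composition and the architecture and randomises only what homology would
add: residue order within segment classes.

## Pairwise alignment and statistics

Alignments are optimal local (Smith–Waterman) alignments under affine gap
costs; a gap of length k costs `open + (k−1)·extend`.  The engine is
Biopython's C `PairwiseAligner`; a brute-force Gotoh DP in the test suite
independently verifies scores on random instances.  Default scoring is
BLOSUM62 with gap open 11 / extend 1 and gapped Karlin–Altschul parameters
λ = 0.267, K = 0.041; a BLOSUM50 10/2 preset is provided for users who
want SSEARCH-style scoring.  'X' scores 0 against everything and carries
no composition weight.  Bit scores are `(λ·raw − ln K)/ln 2` (floored at
0) and E-values are `K·m·n·e^(−λ·raw)` with m, n the two sequence lengths:
pairwise, not database-scaled, so that every downstream filter is
self-contained.  Ties among optimal tracebacks are broken by the engine's
canonical first traceback, which is deterministic across platforms; raw
scores — the quantity every downstream statistic consumes — are unaffected
by the choice.

Redundancy reduction is greedy by descending length with the CD-HIT
identity convention (identical aligned residues / shorter sequence
length); identity over alignment columns alone would let a two-residue
perfect micro-alignment count as 100% identity.

## Topology-preserving shuffles and GEV significance

`shuffle_sequence_topology_preserving` pools the residues of all membrane
segments (TMSs and reentrant loops together — both are hydrophobic
environments) and redistributes them over the membrane positions, and
likewise pools loop residues over loop positions.  Segment boundaries,
lengths, order — and hence all inter-segment distances — never change, and
per-class composition is exactly conserved.  A stricter `per_segment` mode
confines each permutation to its own segment.  Pooling across segments is
the default because it is the stronger null (any arrangement of the
membrane residues is admissible, not just within-segment rearrangements).

The observed score is referred to a generalized extreme value distribution
fitted by maximum likelihood (scipy's `genextreme`; its shape parameter is
the negative of the ξ convention used here) to the scores of the query
against N shuffled subjects.  If the MLE fails, a Gumbel method-of-moments
fallback (σ̂ = SD·√6/π, μ̂ = mean − γσ̂) is used and tagged.  The reported
p-value is the analytic upper-tail probability, not the empirical rank.
The production default is N = 10,000 shuffles; tests and the calibration
suite run scaled-down counts (300–1,000) because the analytic fit
extrapolates the tail reliably from far fewer samples than the empirical
rank would need.

Calibration, measured in the acceptance suite: on matched-topology
non-homolog pairs the fraction with p ≤ 0.05 is close to (and slightly
below) nominal — the analytic fit splits the probability mass of tied
integer scores, which makes it mildly conservative — while true homolog
pairs at 0.5 expected substitutions/site essentially always reach
p ≤ 10⁻³.

## Family profiles and the shuffled-MSA null

Family MSAs are summarised as per-column residue frequency vectors with
background pseudocounts, `f = (counts + w·bg)/(n + w)`, w = 1 by default.
Columns with more than 30% gaps are flagged and excluded from comparison
(the usual poorly-aligned-column trim).  Two profiles are aligned locally
with the column score `s(c₁,c₂) = log₂ Σ_a f₁(a)f₂(a)/bg(a)` and affine
gap costs of 2.5/0.5 bits; by default only membrane-region columns are
compared (`include_loops` restores the rest).  The decoy ensemble permutes
the subject MSA's columns within each consensus segment; because a column
permutation permutes profile columns, each decoy re-alignment reuses the
precomputed column-score matrix (an anti-diagonal-vectorised, score-only
DP keeps this fast).  Significance is the same GEV machinery as above.
The frequency-profile score is a deliberate, self-contained stand-in for
HMM–HMM comparison scores: the inferential weight is carried by the
shuffle-null p-value, not by the raw score convention.

`inject_seed_gaps` projects a pairwise seed alignment's gapping into two
family MSAs: wherever the seed alignment skips k residues of one seed,
k all-gap columns are inserted into the *other* family's MSA at the
corresponding column, giving the two MSAs compatible column geometries
over the seed-aligned region.

## Motif discovery and scanning

Discovery is expectation-maximisation under the one-occurrence-per-
sequence model: a uniform prior over start positions, window likelihood
ratios against the background in the E-step, and a PWM re-estimate with
background pseudocounts (total weight 0.1) in the M-step, iterated to an
objective change below 10⁻⁶ or 200 rounds.  Because of the pseudocounts
the EM-monotone objective is the MAP objective (likelihood × Dirichlet
prior); monotonicity is asserted on every run.  Plain OOPS EM has a
characteristic family of local optima in which every site is displaced by
the same offset (the window straddles the motif); after convergence the
whole site set is therefore tested at uniform shifts (screened by a
single-pass likelihood, refined by full EM) until no shift improves the
objective.  The best of `n_starts` seeded restarts, each initialised from
an observed window, is returned.

Scanning uses an exact null: the distribution of the per-window log-odds
score of a background window, computed by position-wise convolution of
scores discretised to 0.01 bits (error far below any threshold in use).
The best window in a sequence of L residues gets
`p_seq = 1 − (1 − p_window)^(L−w+1)` and `E = p_seq × #sequences`; one
best hit per sequence.  A family's recovery rate is the percentage of
members with a hit at `E ≤ 10⁻⁴`.  Motif quality is reported as
information content and final log-likelihood; no tool-internal motif
E-value is emulated.

## Internal repeats

`split_msa_at_loop` cuts the family MSA at the midpoint column of the loop
following a designated membrane segment (the midpoint maximises distance
from both flanking segments), degaps each half, and projects per-row
topologies from the consensus column labels.  All half-A sequences are
aligned against all half-B sequences; alignments with pairwise E < 10⁻³
are retained.  A retained alignment supports the repeat when (i) at least
`min_segments` membrane segments are ≥ 50%-covered on both sides — the
operationalisation of "fully aligned" that tolerates ragged alignment
ends — and (ii) its score survives the topology-preserving shuffle null
(GEV p ≤ 10⁻³, 300 shuffles by default).  Step (ii) is essential, not
cosmetic: unrelated hydrophobic 3-TMS halves of ~120 residues reach
E < 10⁻³ with full coverage by composition alone in roughly one family in
ten, and the shuffle null removes exactly this class of false support
(measured: 25/25 tandem families detected, 25/25 independent-fusion
controls clean).

## Clustering

Sequence space: the symmetric bit score b(i,j) is self-normalised to
`d(i,j) = 1 − b(i,j)/min(b(i,i), b(j,j))`, clipped to [0,1]; a pair with
no positive-scoring alignment gets d = 1.  Ward linkage is computed with
the Lance–Williams recurrence on distances
(`d(s∪t,w)² = [(n_s+n_w)d(s,w)² + (n_t+n_w)d(t,w)² − n_w d(s,t)²]/(n_s+n_t+n_w)`),
cross-checked in the tests against an independent reference
implementation; exported Newick branch lengths are merge-height
differences, and the tree *topology*, not the branch lengths, is the
meaningful output.  The agglomerative coefficient is
`AC = mean over leaves of (1 − h_first/h_final)`.  The raw bit-score
matrix is returned alongside the distances so alternative transforms can
be explored.

Structure space: `d = (1 − TM)²`, average linkage, cut at 0.04
(equivalently TM ≥ 0.8).

## Structure metrics

Superposition is the SVD Kabsch solution with reflection correction; the
TM-score of a given residue correspondence uses
`d₀ = max(0.5, 1.24·(L_ref − 15)^⅓ − 1.8)` (the standard clamp; the raw
formula is negative for L_ref < 19) and optimises the superposition for
the TM objective by iteratively reweighted least squares
(w = (1 + (d/d₀)²)⁻², 20 fixed rounds).  No structural alignment search
is performed — correspondences come from sequence alignments or are given.

Segment-assignment refinement applies the CA-proximity rule literally: an
unlabeled residue joins a TMS/RL label when its CA is within 1.5 Å of a
CA carrying that label *and* within 3 residues of it, scanning N→C to a
fixed point, TMS winning over RL on conflict, never relabelling an
originally labeled residue.  Note that bonded CA–CA distances are ~3.8 Å,
so at 1.5 Å the rule can effectively only confirm near-coincident traces;
the cutoff is a parameter so users can explore physically looser values
(~4 Å).

## The synthetic generator

The generator defines the study conditions for every test:

- **Composition.** Membrane segments draw residues i.i.d. from a fixed
  table with 80% of its mass on {I,L,V,F,A,M,W,G,C}; loops draw from the
  Robinson–Robinson average-protein background, which is also the
  background model for motifs and profiles.  Mean Kyte–Doolittle values:
  ~1.9 (membrane) vs ~−0.3 (loop).
- **Architectures.** Blueprint factories encode the canonical layouts:
  "3+1" (three clustered 21-residue TMSs, 15-residue connectors, a
  120-residue hydrophilic region, a fourth TMS), "4" (four TMSs, short
  connectors), and a 3-TMS unit for repeat constructions.  TMS length 21
  and RL length 18 follow the observed superfamily means.
- **Evolution.** Each family member derives independently from the
  ancestor: sites are hit with probability 1 − e^(−divergence) and
  resampled from their segment-class distribution; indels (geometric
  lengths, mean 3; rate 0.05·divergence per loop site) occur only inside
  loops, so the membrane architecture is exactly preserved.  Every residue
  records its ancestor coordinate, which lets `family_msa` emit the
  ground-truth MSA (insertions left-justified in their insertion blocks)
  and a consensus column topology — no external aligner is needed
  anywhere.
- **Controls and composites.** Matched-topology non-homolog pairs are
  independent draws from the same blueprint; tandem duplications evolve a
  fresh copy of a unit and concatenate with a loop linker; fusions join
  two given proteins; `convert_tms_to_rl` relabels a segment without
  touching its (hydrophobic) residues.
- **Toy structures.** Ideal α-helices (rise 1.5 Å, radius 2.3 Å,
  100°/residue) per membrane segment, alternating direction; extended
  loop traces; reentrant loops as helix+loop hairpins or two sub-helices
  separated by a 2-residue Gly/Glu turn.  Consecutive CA distances stay
  within 3.8 ± 0.2 Å.

What the generator does *not* emulate: phylogenetic correlation between
members (members are star-shaped around the ancestor), indel hotspots,
realistic secondary-structure-dependent substitution, or side-chain
geometry.  Passing tests therefore certify the statistical machinery
under controlled composition bias, not performance on any particular real
protein family.

## TMS calling: design and a measured limit

The TMS caller works on the Kyte–Doolittle hydropathy profile (window 19,
edge positions carrying the nearest full-window value).  A single
threshold on window values proved far too fragile on realistic
composition: runs bleed across short connectors, extend into loops and
split unpredictably.  The caller is instead a duration-constrained
two-state segmentation: place non-overlapping segments of 15–35 residues,
at least 4 residues apart, maximising the summed hydropathy excess over a
threshold (0.57) minus a per-segment placement cost (5.0) — the Viterbi
decoding of a membrane/loop model with equal-variance Gaussian emissions
and hard duration bounds.  The length cap is what splits long hydrophobic
stretches into multiple crossings.

Calibrated on generator output, the caller reaches ~68% exact
segment-count recovery and ~85% residue-level overlap with the true TMSs.
The exact-count ceiling is a property of the signal, not the decoder: TMS
and loop blocks differ by ~4 standard deviations per decision window, and
a protein offers ~13 such windows, so even an ideal hydropathy-only
classifier miscounts a few percent of segments — compounded per protein.
Reentrant loops are *never* called from sequence (they can be as
hydrophobic as TMSs); RL labels come only from annotations or toy
structures.  Architecture labels group membrane segments separated by
loops shorter than 50 residues ("3+1" etc.); the 50-residue cut cleanly
separates the ~15-residue connectors from the 100+-residue hydrophilic
regions and is exposed as a parameter.

## Evidence reports

`run_evidence_pipeline` executes the seven lines independently — a failing
or inapplicable stage is marked `unavailable` and never blocks the others
— and emits JSON plus Markdown.  All randomness derives from the
configuration's master seed through named streams, so identical
configurations reproduce reports byte for byte.  For a two-family report
the clustering line uses a two-family surrogate of "sharing a major
branch": the median cross-family bit-score distance must sit below 0.9,
i.e. visibly above the unrelated-pair floor of 1.  Problem sizes inside
the pipeline (members per line, shuffle counts) are configurable; the
defaults keep a full report below a minute on one CPU.

## Known limitations

- GEV p-values far below ~10⁻⁶ are extrapolations of a fitted tail; treat
  them as orderings, not calibrated frequencies.
- The profile comparison is frequency-based; it does not model
  insert-state transitions, so very gappy families lose signal beyond the
  30%-gap column trim.
- The repeat finder requires a consensus topology and a stated cut point;
  it does not search cut points.
- Exact segment-count recovery of the TMS caller is bounded by the
  hydropathy signal itself (see above); pipelines that need exact counts
  should use annotated topologies.
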