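# Methods

## The analysis in brief

A receptor protein is modelled as tandem group-B SRCR domains followed by a
transmembrane (TM) segment and a cytoplasmic tail. The pipeline: (1) detect
domains with a profile of the 78-column group-B core; (2) align detected
domains with letter-labelled references and project onto the core columns;
(3) estimate divergences as uncorrected p-distances with bootstrap SEs;
(4) build a neighbor-joining (NJ) tree with bootstrap clade support;
(5) assign each query domain a nomenclature letter from its clade;
(6) render architecture strings and family-type calls; (7) call TM segments
and scan the tail for tyrosine motifs.

## Domain model and scanning

The model is built from a reference alignment of letter-labelled domains:
per-column residue frequencies with a uniform pseudocount (0.5), scored
against a query residue as the frequency-weighted Gonnet-250 substitution
score (the classic profile–sequence score of progressive aligners). The
eight cysteine columns are those where cysteine is modal with frequency
≥ 0.5; fewer than eight is rejected as "not a group-B reference".

Scanning aligns the *entire* profile against substrings of the protein
(glocal dynamic programming: free ends in the protein, affine gap costs of
12/1 in matrix units for both deleted core columns and inserted protein
residues). The protein is tiled greedily: the best-scoring candidate among
all not-yet-consumed intervals is accepted if its score reaches the
threshold and its span lies in the 78–110 residue window (± 6 residues of
edge slack), then its flanks are searched recursively. Ties prefer the
smaller start coordinate. The acceptance threshold defaults to 40% of the
model self-match score (sum of per-column maxima) — calibrated on the
generator so that domains as diverged as p ≈ 0.8 are still accepted while
linkers are not. Cysteine presence is read off the aligned core columns and
never gates acceptance: domains missing up to four cysteines are reported
with their missing set and "B_atypical" call (more than four missing is
flagged "A_like" and is outside the model's intent).

## Alignment

Pairwise: global Needleman–Wunsch with affine gaps, gap open 10.0, gap
extension 0.10, Gonnet-250 matrix — delegated to Biopython's
`PairwiseAligner`, with `X` (unknown residue) extended into the matrix at
score 0 so genomic-prediction gaps are alignment-neutral. Terminal gaps are
penalized by default (`penalize_terminal_gaps=False` gives end-free
alignment). Determinism comes from reporting the first alignment in the
aligner's canonical enumeration order; on short sequences the score is
verified against exhaustive enumeration of all affine-gap alignments.

Multiple: UPGMA guide tree over pairwise p-distances (deterministic
smallest-pair tie-break), then profile–profile merges scored by
frequency-weighted sum-of-pairs with the same gap costs. Every output row
is asserted to ungap back to its input. `trim_to_core` projects any
alignment onto the 78 core columns through a designated reference row, so
all distance work shares a fixed column count L = 78.

## Divergence and standard errors

The working distance is the uncorrected p-distance with pairwise deletion:
columns where either row holds `-` or `X` are excluded per pair, so an
indel in one domain does not delete columns globally. A pair with no
comparable columns is reported missing, never 0. The tabulated SE of a
p-distance is estimated by resampling alignment columns with replacement
(default B = 1000; B = 10,000 for the headline check) and taking the
standard deviation of the resampled distances; it converges to the binomial
closed form `sqrt(p(1-p)/L)`, which ships as `analytic_se` and is used as
the independent check. The transcribed published tables are consistent with
this reading: at L = 78, 94% of the 476 (p, SE) cells match the closed form
to printed precision and no cell deviates by more than 0.0035 — the size of
Monte-Carlo noise of a bootstrap SE at a few hundred replicates — while
neighbouring values of L fit far worse. The residual 6% therefore reflects
the published values being bootstrap estimates (and possibly occasional
pairwise-deletion L < 78), not a different distance model; the stricter
all-cells-at-0.0005 reading is asserted in the acceptance suite and fails
on exactly those cells.

For tree building, p can be corrected: Poisson `d = -ln(1-p)`, or
`jtt_like` — the time at which the JTT empirical rate matrix (shipped as
exchangeabilities + equilibrium frequencies, PAML residue order, scaled to
one expected substitution per unit time) yields an expected
different-site fraction equal to p, solved by bracketed root finding on
`1 - Σ π_i P_ii(t)`. This equals the maximum-likelihood distance when the
data are reduced to differ/agree counts; saturation (`p ≥ 1 - Σ π_i²`)
returns infinity, flagged.

## Neighbor joining and support

Standard Saitou–Nei Q-criterion agglomeration, ties broken by the smallest
(row, column) index pair; the result is stored with a trifurcating root.
Negative branch lengths are retained with a warning (a config flag clamps
them to zero, compensating on the sister edge). On additive matrices the
method is exact (topology and lengths), which the tests exploit as an
oracle alongside a least-squares brute-force topology search on four taxa
and a cross-check against scikit-bio's implementation. Bootstrap support
of an internal edge is the fraction of B column-resample NJ trees
containing the same bipartition; bipartitions are canonicalized on the
unrooted tree and zero-length internal edges are treated as soft
polytomies (no bipartition), so identical sequences yield no supported
splits.

## Letter assignment

Clades are handled as *bipartition sides* of the unrooted tree rather than
rooted subtrees: the NJ root is an artifact and can fall inside a letter
clade (observed in testing: ancestor-walking left 20/112 domains of one
family unassigned; the side formulation assigns all of them). For each
query, the smallest supported side (support ≥ 0.70 by default) containing
it and at least one reference donates its letter if its references are
unanimous. Ties among equal-sized minimal sides prefer, in order:
unanimous references, then a pure d/d′ mixture, then higher support, then
a lexicographic side ordering — the d/d′ mixture resolving by position
(d′ if the query is its protein's C-terminal domain, d otherwise),
encoding the convention that d′ is the membrane-proximal, terminal domain.
Letter-mixed minimal clades leave the query undesignated.

Undesignated queries forming supported reference-free sides of ≥ 2 queries
share one freshly allocated letter per inclusion-maximal side; allocation
runs alphabetically from `o`, skipping reference letters, ordered by first
query occurrence. A positional pass then promotes an interior undesignated
domain whose two assigned neighbours match a unique middle letter across
the reference architectures; clade and new-letter calls are never
overridden. Family calls use diagnostic letters with fixed precedence:
k → CD163A-like; a with any of m/l/n → hybrid; a → WC1-like;
m/l/n → CD163c-α-like; otherwise unclassified.

## Membrane topology and motifs

TM segments come from mean Kyte–Doolittle hydropathy in a 19-residue
sliding window with cutoff 1.6: runs of above-cutoff window centres are
reported, padded to at least the window length, merged when overlapping.
This is a transparent stand-in for dedicated TM predictors: it is meant to
find the single strong TM of these receptors, and externally determined
coordinates can be supplied and are passed through verbatim. The
cytoplasmic domain is everything C-terminal to the last TM segment. The
WC1-type motif scan matches every (overlapping) tetramer
Y-(Q/E)-(D/C/E)-(I/L) — a 12-member class the tests enumerate exhaustively
as an oracle — and reports threonine-fourth-position near-misses under a
separate tag that never counts as a motif. Literal motifs (e.g. `YREM`,
the CD163A tail motif) are matched exactly at every position.

## Synthetic families: what they emulate and what they do not

`FamilyConfig` defaults are the study conditions: 13 reference letters,
78-column core with the cysteine scaffold at fixed columns, between-letter
prototype divergence 0.55 (the tables' inter-letter values span ~0.45–0.82)
and within-letter rate 0.10 (intra-letter diagonal 0.09–0.23); three
published architectures (WC1 `a-b-c-d-e-d-b-c-d-e-d'`, CD163A
`h-i-j-k-b-c-d-e-d'`, CD163c-α `m-l-b-c-n-d-e-d'`) with four copies each;
hydrophilic linkers of 5–12 residues; an optional 21-residue hydrophobic
TM; a tail motif drawn from the WC1 tetramer class (or `YREM`, or none);
optional cysteine dropout (one non-anchor cysteine → serine, recorded in
truth).

Prototypes evolve along a random balanced binary "letter tree" with exact
per-edge substitution budgets in coverage form; pendant budgets are set so
every leaf has equal root-to-leaf coverage and pairwise divergence centres
on the target. Because per-column substitution noise (σ ≈ 0.05 per pair)
would still scatter some of the 78 letter pairs outside the ± 0.08 band, a
bounded repair pass nudges the worst pair one column at a time (too close:
substitute an agreeing column; too far: copy one residue across). Two
regimes follow:

- **Uniform regime** (default, `enforce_divergence_band=True`): realized
  inter-letter distances all fall in [0.47, 0.63], matching the
  near-uniform published tables — the right difficulty for testing letter
  assignment, where clade structure between letters is nearly star-like.
- **Hierarchical regime** (`enforce_divergence_band=False`, larger
  `letter_tree_edge_columns`): the letter tree's internal edges carry
  enough signal to be recoverable; the tree-recovery check runs at 6
  letters, 2 copies per letter, within-letter rate 0.03 and 10 columns per
  internal edge, where NJ recovered the generating topology (RF = 0) in
  30/30 generation seeds.

Substitutions draw uniformly from the 18 non-cysteine alternatives, so a
copy's expected p-distance to its prototype is exactly
`rate × (1 − 8/78)`. The generator writes full truth (coordinates,
letters, copy tree with within-letter cherries, motif positions) and is
byte-reproducible from its seed.

What the generator does **not** emulate: insertions/deletions inside
domains (real SRCR domains vary 78–110 aa; detection of length variants is
exercised only through gap handling in alignment), signal peptides,
alternative splicing, compositional bias, or gene conversion as a
population process (an optional deterministic domain copy-paste stands in).
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the published divergence structure, not robustness to
every feature of real genomic data.

Two deterministic stand-ins (`bovine_cd163a_standin`,
`bovine_cd163c_alpha_standin`) encode the stated organization of the two
bovine receptors — 9 domains with the 8th missing C2+C7 and a cytoplasmic
YREM; 8 domains with the 5th missing C2+C7 and a cytoplasmic YEDI — for
tests that need concrete receptor instances. They are synthetic surrogates,
not the real sequences.

## Numerical and design choices

- L = 78 core columns, frozen after the table-wide SE consistency analysis
  above.
- Scan threshold 40% of self-score; profile gap costs 12/1; edge slack 6.
- Bootstrap B defaults: 1000 (SEs), ≥ 100 (tree support); seeds mandatory
  wherever resampling occurs; per-pair bootstrap seeds are derived
  deterministically from the run seed.
- Clade support threshold 0.70 (config) — the nomenclature source used
  posterior probabilities without a stated cutoff, so this is a calibrated
  choice, not a published constant.
- Problem sizes in the test suite (12 proteins × ~9 domains, B = 100–10,000,
  6-letter tree-recovery families) were chosen so the full suite exercises
  every stage end-to-end in well under a minute of compute per module.
- Degenerate inputs: empty FASTA, all-gap column pairs, saturated
  distances, trees of fewer than three taxa, proteins without TM segments
  all raise typed errors or flagged results rather than silent zeros.

## Known limitations

- Pairwise-deletion p-distances are not guaranteed additive; NJ on heavily
  gapped alignments can produce negative branch lengths (retained,
  warned).
- The hydropathy TM rule is deliberately simple; proteins with marginal or
  multiple hydrophobic stretches should use user-supplied coordinates.
- New-letter allocation depends on bootstrap support topology; in trees
  where reference classes interleave poorly-supported query clusters, the
  method prefers leaving domains undesignated over inventing letters.
- The aligner's tie-break among co-optimal alignments follows the
  underlying library's deterministic enumeration rather than a published
  convention; percent-identity figures at these divergences are
  insensitive to it.
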