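# Methods

This note documents the models behind `metacomp`, the parameters that
matter, the design choices made where a convention had to be fixed, and
what the synthetic-data harness does and does not show about real data.

## Dataset distance from bit scores

The unit of comparison is a whole read dataset. For datasets *A* and *B*
every read of each is aligned against all reads of the other and of its
own dataset; hits are filtered to percent identity **strictly above 70%**
and alignment length **strictly above 100 bp** (both thresholds strict —
this filter is conventionally quoted with ">"), and bit scores are summed
to the totals *AB*<sub>s</sub>, *AA*<sub>s</sub>, *BB*<sub>s</sub>. The
distance is the set-theoretic Jaccard on bit-score mass,

    D = 1 − AB_s / (AA_s + BB_s − AB_s),

with the Sørensen–Dice variant `1 − 2·AB_s/(AA_s + BB_s)` available via
`form="dice"`. Three conventions are fixed here and exposed as options:

- **Summation policy** (`best-per-query` default): each query read
  contributes its single best-scoring hit. `best-per-pair` and
  `all-hsps` are provided because the aggregation used by earlier
  whole-dataset comparisons is not standardized.
- **Directionality**: *AB*<sub>s</sub> is the mean of the A→B and B→A
  totals, making D symmetric by construction.
- **Self-hits**: a dataset aligned against itself includes each read's
  perfect self-match; these are kept in *AA*<sub>s</sub> (toggle
  `include_self_hits=False` to drop them). Keeping them guarantees
  *AB*<sub>s</sub> ≤ *AA*<sub>s</sub> per direction; because the
  symmetrized cross total can still marginally exceed the smaller self
  total when dataset sizes differ, `distance_matrix` clips
  *AB*<sub>s</sub> at min(*AA*<sub>s</sub>, *BB*<sub>s</sub>) before the
  ratio, while the bare `jaccard_distance` function treats that situation
  as an input error.

D is a ratio of bit-score sums, so it is exactly invariant to any uniform
positive rescaling of bit scores — the alignment scoring parameters move
individual scores but not the distance structure.

Note that D(A, B) does not approach 0 merely because A and B are drawn
from the same genome pool: two independent read samples of the same
community still differ read-by-read, and each dataset's self-comparison
contains perfect self-hits that cross-comparisons cannot match. D = 0 is
reached only in the duplicate-dataset limit (identical reads under two
labels).

## Alignment engine

The built-in aligner follows the classic seed-and-extend recipe:

- exact **k-mer seeding** (default k = 11) on both strands, seeds grouped
  per (subject, diagonal) and merged;
- **ungapped X-drop extension** (default X = 20 score units) with match
  +1, mismatch −2;
- optional **banded gapped refinement** (`gapped=True`): a banded
  Smith–Waterman (band ±8, window ±200 bp around the ungapped HSP) with
  affine gaps, open −5 / extend −2, a gap of length L costing
  `open + L·extend`;
- one best HSP per (query, subject) pair by default; `all_hsps=True`
  reports every HSP.

Raw scores are normalized with Karlin–Altschul parameters λ = 1.28,
K = 0.46 — ungapped-theory values applied to all scores as an
approximation — giving `bits = (λS − ln K)/ln 2` and
`E = m·n·2^(−bits)` with m the query length and n the total subject
length. Hits with E above 10 are suppressed. None of these defaults
affects the distance structure (see scale invariance above); they are
configurable because no standard word size or scoring scheme exists for
this kind of comparison. Coordinates are 1-based inclusive;
reverse-strand hits carry `s_start > s_end` (the 12-column tabular
convention), and identity is `100 × matches / alignment length` with gap
columns counted in the length.

The aligner handles the nucleotide case only. Translated (protein-level)
recruitment is approximated, where needed, by lowering the nucleotide
identity threshold rather than by six-frame search; percent identities
from the two approaches are not directly comparable, which is why the
recruitment thresholds are exposed as parameters.

Edge-effect corrections, composition-adjusted statistics and gapped
Karlin–Altschul parameters are deliberately out of scope; external
aligners can be substituted through the tabular ingest path whenever
full-fidelity statistics matter.

## Neighbor joining

`neighbor_joining` implements Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion. Ties in Q are broken deterministically by
the ordered pair of node labels; negative branch lengths are clamped to
zero (presentation choice, matching common practice); the final three
nodes are joined by the three-point formulas into a trifurcating root, so
the result is an unrooted tree. On an additive matrix the generating
topology and branch lengths are recovered exactly. Outgroup rooting
splits the outgroup's pendant edge at its midpoint, making the outgroup a
direct child of the root.

## GC profiling

GC content is `100·(G+C)/(A+C+G+T)` per read; N bases are excluded from
numerator and denominator (undetermined bases carry no compositional
signal), and a read with no A/C/G/T bases has undefined GC. Histograms
use half-open fixed-width bins over [0, 100] (last bin closed). Mode
detection smooths the counts with a Gaussian kernel (bandwidth 2 GC
points by default) and keeps local maxima with prominence at least 5% of
the smoothed maximum; defaults were chosen so that two community modes
~20 points apart (the 45%/65% case) are resolved while binomial
per-read noise (sd ≈ 2.8 points for a 325 bp read at 50% GC) is not
reported as structure. The low/high split at 50% assigns reads exactly
at the threshold to the low side — interval wording with open intervals
on both sides leaves the boundary unassigned, and a total partition is
required; the tie rule is a documented convention, not data-derived.

## Fragment recruitment and overlap

Recruitment keeps hits at **identity ≥ 95% and length ≥ 50 bp** (both
inclusive — these thresholds are quoted as minima, unlike the strict
distance filter), one best hit per read, each contributing a point at the
subject-coordinate midpoint. Genome ranking is by recruited-read count,
descending, ties by genome id. The dataset-overlap fraction counts query
reads with at least one hit at identity **strictly above 90%** covering
at least half the read; it is monotone non-decreasing as either threshold
relaxes.

## Taxonomic classification

The 16S rule engine is total — every read gets exactly one call:

1. discard alignments ≤ 100 bp (strict);
2. take the best remaining hit **by bit score** to a *named* record (one
   with a genus whose annotation does not contain "uncultured" or
   "unidentified"; ties by ascending record id);
3. identity > 95 → that record's genus; 90 ≤ identity ≤ 95 → its higher
   taxon; identity < 90 → unidentified. Boundary values 95 and 90 fall in
   the higher-taxon band, the conservative reading of a ">95 / <90" rule
   pair.
4. reads whose passing hits are all to uncultured/unidentified records,
   or with no passing hits, are unidentified (with a note distinguishing
   the cases).

Best-hit binning of bulk reads uses e-value ≤ 1e-5 and alignment ≥ 50 bp,
assigns the best bit-scoring passing hit's taxon (ties by ascending
subject id), and leaves reads with no passing hit unclassified. Profile
tables report per-taxon counts with percentages of classified and of
total reads. No lowest-common-ancestor logic is attempted — the binning
rule is deliberately the simple best-hit one.

## Enrichment statistics

`fisher_two_sided` computes the exact two-sided p-value by summing, over
all 2×2 tables with the observed margins, the hypergeometric point
probabilities not exceeding the observed one (with 1e-7 relative slack —
the convention used by common profile-comparison tools; mid-p is not
used). The pmf is evaluated through vectorized log-binomials. A table
with an all-zero row or column carries no evidence and returns p = 1
rather than raising: profile comparison imputes zero counts for absent
categories and must tolerate them.

`storey_qvalues` estimates π0 = min(1, #{p > λ}/((1−λ)m)) at a single
λ = 0.5 (the spline-smoothed estimator is deliberately not implemented;
a fixed λ keeps the procedure deterministic and transparent), then
applies the step-up construction q(i) = min over j ≥ i of π0·m·p(j)/j on the sorted
p-values. With π0 pinned to 1 the result is exactly
Benjamini–Hochberg.

`compare_profiles` passes a category when q ≤ 0.05, its sequence count
reaches 100, and the proportion ratio exceeds 2. The count rule is
interpreted as **combined across both datasets** by default
(`min_seqs_mode="per-dataset"` for the stricter reading) — the filter is
conventionally stated without specifying which. Domain abundance ratios
are `(countX/totalX)/(countY/totalY)` with a 0.5 pseudocount substituted
only for zero counts, and such rows flagged.

## Synthetic data: what it emulates, and what it does not

Genomes are i.i.d. base sequences with P(G) = P(C) = GC/2; realized GC
concentrates within ±3 points of target above 10 kb. Reads follow a
normal length model, mean 325 bp and sd 75 bp — the pyrosequencing-era
profile — truncated by resampling to [60 bp, genome length], so every
simulated read survives the 60 bp analysis filter. Errors are i.i.d.
**substitutions only**: 454-style homopolymer indels are not modeled.
This keeps identity accounting exact (an error rate of e gives expected
identity 100·(1−e) under ungapped alignment), which is what the
threshold-rule classifiers and recruitment filters are tested against.
Paired communities draw `round(shared_fraction·n)` genomes from a common
pool, the rest privately, with GC targets alternating between the two
modes (0.45/0.65 by default) so each read set is bimodal; abundances are
uniform. Marker references are mutated copies of a single seed marker
(1.5 kb, 16S-scale) at an exact substitution divergence
(`round(divergence·length)` distinct positions); named entries carry
genus labels, uncultured ones the literal annotation "uncultured
bacterium". Profile pairs are multinomial draws with planted
per-category fold changes applied to one side and renormalized.

Passing tests on this harness demonstrates that the *rules and statistics
are implemented correctly* and that each stage recovers planted structure
under idealized noise. It does not demonstrate robustness to real-data
phenomena the generators omit: indel-rich error profiles, conserved
regions shared between unrelated genomes, rRNA secondary-structure
conservation (which makes real 16S identity thresholds subtler),
database mislabeling, or abundance distributions with long tails.

## Problem sizes and numerical conventions

The package's own demonstrations and checks run at desk scale, chosen as
the smallest sizes at which the statistical claims are comfortably
resolved: distance sweeps use 4-genome communities of 10 kb genomes and
120–150 reads per dataset over several seeds; GC mode recovery uses
10,000 reads; recruitment/binning recovery uses a 3-genome, 30 kb,
3,000-read community at 1.5% error; enrichment error rates use 200
categories × 10^4 counts over 50–100 simulations; the end-to-end CLI
demo uses 3 datasets × 800 reads over 5 genomes of 15 kb. The power
simulation for the enrichment filter raises the planted category's
baseline proportion to 0.03 so its expected count (~300) is large enough
for a 3-fold change to clear the q/count/ratio filter; with a uniform
baseline at these sizes the expected count (50) sits below the
100-sequence rule by construction.

Determinism: every generator takes an explicit seed and is
bit-reproducible; pipeline runs with the same seed and configuration
write byte-identical outputs (the manifest, which records wall-clock
times, is excluded from that guarantee). Floating-point output uses
`repr` round-tripping, so TSVs are lossless. Degenerate inputs raise
early with named causes: empty subject collections, zero post-filter
self-scores (distance undefined), empty read sets for GC profiling,
zero-total profiles, non-symmetric matrices.
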