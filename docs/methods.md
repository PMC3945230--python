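# Methods

`mosaicscan` quantifies recent sequence exchange between phage and
prophage genomes and asks whether those exchanges were made by
homologous recombination.  This note records the model, the estimators,
the numerical choices, and what the synthetic validation does and does
not demonstrate.

## The detection model

Two phage genomes that diverged long ago share a low background
identity *b* (often near or below the limit of reliable alignment).  A
*mosaic* is a segment the two genomes exchanged recently: operationally,
a local alignment of at least 100 bp with strictly more than 90%
identity.  If the exchange happened by homologous recombination, the
crossovers necessarily sat inside pre-existing partial homology, so the
sequence immediately flanking the mosaic should be more similar than
*b* — an *HR trace*.  A flank carries a trace when, after global
re-alignment of the 2-kb flanking sequences, at least one 50-bp window
reaches *b* + 10 percentage points.  The 50-bp window matches the scale
of the minimal pairing segment that single-strand-annealing
recombinases (Redβ-like) require; the +10-point offset separates a
genuine homology patch from ordinary window-to-window fluctuation.

## Pipeline stages

1. **Relatedness screen.** Fragment ANI in the Goris style: the smaller
   genome is cut into 1000-bp fragments (1000 rather than the original
   1020 — a round number; configurable), each is locally aligned to the
   larger genome, and a fragment contributes when its best hit covers
   ≥70% of it.  ANI = mean identity of contributing best hits;
   coverage = percent of fragments contributing.  Pairs with ANI > 92%
   and coverage > 80% are redundant (the lexicographically larger
   genome leaves the cohort); temperate/defective pairs above 70%/50%
   and virulent pairs above 68%/48% are excluded as too related for the
   flank signal to be distinguishable from vertical homology.  Mixed
   temperate–virulent pairs use the temperate/defective thresholds
   (configurable).  The relaxed scoring scheme (match +3, mismatch −4,
   gap open 5, extend 2, word 10) keeps the expected per-column score
   positive down to ~57% identity, which is what lets ANI reach the
   60% range at all.
2. **Mosaic detection.** A seed-and-extend local search: exact word
   seeds (word 11, megablast-like +1/−2 scoring) on both strands,
   greedy diagonal clustering (diagonal drift ≤ 30, seed gap ≤ 200 bp),
   then an affine-gap Smith–Waterman on each cluster's neighborhood
   (±200 bp margin).  Hits ≥ 100 columns with identity > 0.90 are
   mosaics; overlapping redundant hits keep the higher score.
3. **Hit-extent refinement.** Raw local extension under +1/−2 stays
   score-positive through anything above ~67% identity, so a hit would
   silently absorb flanking partial homology — exactly the signal the
   trace caller needs to find *outside* the hit.  Reported boundaries
   are therefore the identity-consistent core: first the maximal-sum
   column subsegment with matches scored +1 and non-matches
   −t/(1−t) at t = min_identity − 0.025, then a terminal polish that
   walks each end inward until the outermost 25 columns meet
   min_identity.  Both steps are deterministic; t sits slightly below
   the reporting threshold so legitimate hit ends whose local identity
   dips toward it are not clipped.
4. **IS filtering.** High-identity IS copies are transposition, not
   exchange.  IS annotations come from per-genome intervals or from
   mapping an IS catalog FASTA (≥90% identity over ≥80% of the catalog
   sequence); a mosaic is discarded when ≥50% of its span on either
   genome is IS.
5. **Trace calling.** Flanks are taken outward from each mosaic
   boundary (strand-consistently; boundary-first orientation) up to
   2 kb, re-aligned globally under the relaxed scheme (flanks are by
   construction diverged, so the permissive matrix is the right one),
   profiled in successive non-overlapping 50-bp windows with gap
   columns counted as mismatches, and the flank's background *b* is its
   own median window identity — a per-locus, anchor-resistant estimate
   (an anchor occupying ≤25% of the windows cannot move the median).
   A side has a trace when a window within `proximal_cols` of the
   boundary reaches *b* + δ (δ = 0.10 absolute) and the background is
   not saturated (*b* + δ < 1 − 1/50).  Flanks under 500 bp (genome
   ends) are untestable and leave the denominator.

## The null model, and why proximal search matters

Under gap-free background divergence the matches in a 50-bp window are
Binomial(50, *b*), so the chance a window reaches *b* + 0.10 is
q = P[Bin(50, b) ≥ ⌈50(b+0.10)⌉] — about 0.08–0.10 for *b* between
0.55 and 0.65, because +10 points is only ~1.4 binomial SD at this
window size.  A search over all 40 windows of a 2-kb flank therefore
qualifies *somewhere* with probability ≈ 0.98: at moderate background
identity the whole-flank search is saturated and a trace call carries
almost no information.  The instrument becomes informative exactly in
proportion to how tightly the search is confined to the boundary,
which is where recombination mechanics put the homology in the first
place.  The analysis scripts and validation experiments therefore use
`proximal_cols = 250` (five windows; per-side null rate ≈ 0.3–0.4) or
100 for minimal-anchor power measurements, while the library default
remains the full flank for users who want the permissive behavior.
`random_trace_probability` reports
1 − (1 − q)^(windows × sides) computed in log-space; a column-permutation
estimate of the same tail (`permutation_window_tail`) is provided as a
model-free cross-check and agrees with the binomial tail within
Monte-Carlo error on indel-free data.

Two instruments, one statistic: the binomial null is exact on the
*positional* site correspondence (the known, gapless base pairing of a
simulated flank).  Global re-alignment redistributes gaps to maximize
matches, which lifts the low-identity windows more than the high ones,
shrinking window variance — the end-to-end trace rate on anchor-free
flanks lands measurably *below* the binomial prediction (≈0.90 vs
≈0.98 at b = 0.60 over 40 windows).  Calibration is therefore asserted
two-sided on the positional instrument and one-sided (conservative) on
the re-aligned route; null probabilities reported by the pipeline are
upper bounds for the realigned caller.

## The synthetic cohort

`simulate_cohort` emulates the recombination scenario directly.  Per
pair: a random ancestor (uniform base composition) mutates
independently into two genomes at the per-site rate giving pairwise
identity *b* = 0.60 (a site stays equal with probability
(1−d)² + d²/3); mosaics are planted by copying a segment from genome 1
into genome 2 at 95–99% identity (lognormal lengths, median 450 bp,
clipped to 150–800 bp); 200-bp anchors at *b* + 0.20 are written flush
against each mosaic boundary; optional identical IS-like repeats
(1200 bp) land at independent positions in both genomes; optional
locally-compensated indels break colinearity without shifting any
truth coordinate.  Defaults are the study conditions: 10 pairs of
45-kb genomes, 3 mosaics per pair, anchors on both sides, no IS, no
indels.  Feature placement keeps 2.2 kb from genome ends and 2.5 kb
between features so flanks never overlap a neighboring feature.

*Trace masking* emulates a later exchange overwriting one anchor with
unrelated sequence.  Masking decisions and replacement sequence come
from a per-mosaic child generator keyed by (seed, pair, mosaic), so the
main random stream never depends on `p_mask`: cohorts at increasing
`p_mask` under one seed are identical except that the masked set grows
monotonically.  That nesting is what turns "more masking shifts
two-trace calls to one-trace calls" into a deterministic comparison
rather than a noisy contrast of independent cohorts.

The truth tables record *realized* coordinates and identities
(mutation draws, not targets).  Scoring against truth: a detection
matches a planted mosaic when it covers ≥ 80% of the planted segment
and stays within the planted mosaic-plus-anchor span (+15 bp).
Containment replaces a strict reciprocal-overlap rule deliberately: an
anchor only 10–15 points below the mosaic's identity can carry
stretches locally indistinguishable from the exchange, so a hit
boundary inside the anchor is correct detector behavior, while the
containment requirement still rejects any hit that is not the planted
exchange.

### What the simulation does not show

Uniform per-site divergence has no rate heterogeneity (a two-rate
mixture is available but off by default), no gene structure or codon
bias, uniform GC, and phylogenetically independent pairs.  Passing
recovery tests therefore demonstrates the estimators' correctness
under their stated model, not robustness to conserved-gene mimicry of
anchors, to repeat families beyond the planted IS model, or to real
prophage decay.  Real-data thresholds (the 90%/100-bp rule, the
exclusion grid) are honored as stated but their biological adequacy is
not re-derived here.

## Numerical choices

- Coordinates: 0-based half-open internally, 1-based inclusive in all
  written tables.
- Gap convention: a gap run of length L costs open + L·extend
  (open 5, extend 2 in both schemes).
- Gap columns count as non-matches in identity, window identity and
  perfect-segment runs; `N` matches nothing, including another `N`.
- Global alignment is Biopython's `PairwiseAligner` (affine Gotoh);
  the traceback is its canonical first path, deterministic for fixed
  input.  Scores are verified exactly against an independent
  plain-Python DP in the tests.  Inputs over 10 kb are refused
  (quadratic guard); callers chunk.
- Local search guarantees are seeded: a segment with no exact shared
  word (word 11 at <~80% identity over short lengths) produces no hit.
  Validation asserts ≥95% of the exhaustive Smith–Waterman optimum on
  seeded searches.
- Perfect-identity segments (for MEPS counts) are maximal runs of match
  columns; both mismatches and gaps break runs (configurable reading
  was considered and rejected: an indel interrupts pairing just as a
  mismatch does).  MEPS thresholds default to the lower bounds of the
  published ranges, 23 bp (Redβ) and 31 bp (RecA), and are parameters.
- Mosaic density divides the count by the mean of the two genome
  lengths per 10 kb (min/max available); mean is symmetric and stable
  when pair lengths differ.
- Category summaries: medians over kept mosaics; the per-category null
  probability uses the binomial model at the category's mean flank
  background over all tested windows.

## Problem sizes

Validation experiments are sized to be decisive yet quick on one CPU:
50 oracle pairs (~100–260 bp) for exact DP agreement, the default
10-pair/45-kb cohort (30 planted mosaics) for recovery, 200 simulated
flank sides per condition for calibration and power, and 6-pair/20-kb
cohorts for the masking contrast.  The full suite runs in a few
minutes; `scripts/acceptance.py` in about one.

## Known limitations

- The trace caller's resolution is one window: a real homology patch
  shorter than ~35–40 bp is usually invisible, and boundary placement
  inside an anchor is ±tens of bp by nature.
- The binomial null ignores alignment-induced window correlation (it
  is conservative for the realigned caller, see above) and assumes a
  single background rate per flank.
- ANI on pairs near 60% identity has low fragment coverage under any
  scoring; exclusion decisions there rest mostly on the coverage
  criterion, as intended by the screen's design.
- No E-value model: hit significance at the 90%/100-bp threshold is
  enforced by the threshold itself (a ≥100-bp, >90% segment between
  unrelated 45-kb genomes has vanishing probability by chance).
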