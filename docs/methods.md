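# Methods

## Problem setting

tRNA-derived fragments (tRFs) guide Argonaute to mRNAs through seed
pairing: tRF nucleotides 2–7 bind a perfectly complementary hexamer (the
*seed match*) in a 3′-UTR.  The package predicts which seed matches are
functional.  Ground truth for training comes from chimeric AGO reads
(CLASH / CLEAR-CLIP), in which the tRF and a fragment of its bound
target are ligated into one sequencing read.

Coordinates are 0-based half-open on the transcript's 5′→3′ strand
everywhere internally; sequences are held in the RNA alphabet (T→U on
input).  Windows that run off a UTR end are truncated and used as-is,
never padded or discarded; distance weights still count from the site.
N residues are excluded from composition denominators and seed matches
may not overlap an N.

## Chimeric-read decomposition

Reads are split by exact longest prefix-or-suffix match against the tRF
catalog — no mismatches, bulges or partial tRF matches.  Exact matching
replaces heuristic local alignment because the inclusion rule is already
"no mismatches or bulges, catalog tRFs only", making alignment scores
superfluous and the decomposition deterministic.  The leftover fragment
(≥ 6 nt) is mapped exactly to the 3′-UTR set; multi-mapping fragments
are kept and flagged (a switch drops them).  A pair is positive only
when the mapped fragment contains a perfect seed match of the decomposed
tRF strictly inside the fragment interval; identical (tRF, transcript,
site) triples deduplicate.  tRF-3 sequences are matched with their
3′-CCA as stored in the catalog.  Reads are assumed adapter-trimmed; an
exact-duplicate collapser is provided.  Fragments mapping to no 3′-UTR
are discarded with a reason code rather than re-searched elsewhere in
the transcript.

## Background and negatives

The background is every seed match of every catalog tRF on transcripts
hosting **no** positive pair (transcript-level exclusion).  When
multiple 3′-UTR isoforms exist, the one with the most 3P-seq tags wins,
ties going to the longer UTR and then input order.  Negatives are drawn
at 5× the positive count: background pairs are ranked by host-transcript
tag count, the top pool (twice the requested size, extended through rank
ties) is sampled uniformly without replacement.  Ranking-then-sampling
reconciles "randomly chosen" with "the most tags": the pool restricts to
well-supported isoforms, the draw within it is uniform and seeded.

## Feature roster

108 features in four families (the registry is versioned and
configurable; the genetic algorithm operates on whatever roster is
active):

- **Site sequence** — indicators for the position-8 match (the UTR base
  immediately 5′ of the site complementing tRF position 8; antiparallel
  geometry puts tRF 3′ positions upstream of the site), position-1 match
  and position-1 A (the base immediately 3′, opposite tRF position 1;
  the two flags are independent — both hold when tRF position 1 is U and
  the base is A); one-hot base identities at ±1 and ±2; GC percent of
  the 35-nt upstream, 15-nt downstream and upstream-excluding-10-nt
  windows; the distance-weighted AU score S_AU = Σ 1/d for the same
  three windows (the exclusion window exists because the 10 nt
  immediately upstream are dominated by 3′-tRF pairing rather than AU
  context); mono- and dinucleotide composition of both windows;
  distances to the UTR 5′ end, 3′ end and nearest end.
- **Transcript** — length, GC and seed-match frequency of the 3′-UTR,
  CDS and 5′-UTR, plus 3′-UTR mono-/dinucleotide composition.
  Seed-match frequency is normalised per 1000 nt because raw counts
  would duplicate the separate length feature.
- **tRF** — catalog length, whole-tRF GC, seed GC, target-site
  abundance over the supplied 3′-UTRome and (when a genome sequence set
  is supplied) the genome; absent genome ⇒ missing value.
- **Duplex / accessibility** — duplex MFE, number of tRF positions
  paired and the variant excluding seed positions 2–7 (both exposed as
  features since either reading of "bases paired beyond the seed" is
  defensible), exposed nucleotides at the site and in the ±10-nt flanks,
  and the opening energy of the site.

Missing values (empty regions, truncated windows, absent genome) stay
NaN through assembly and are imputed with training-partition medians
inside each cross-validation fold, so no test-fold information reaches
the imputer or scaler.

## Bundled energy model

Production pipelines would use a full nearest-neighbour folding package;
the bundled model is deliberately small so that every thermodynamic
number in the test suite is reproducible by exhaustive enumeration.
Energy accrues only from stacked adjacent pairs: G:C on G:C −3.0, G:C on
A:U −2.0, A:U on A:U −1.0, any stack touching a G:U wobble −0.5
kcal/mol; every internal loop / bulge / multibranch event costs a flat
+4.0; hairpin loops need ≥ 3 unpaired bases; dangling ends are free.
The stack table can be overridden from a TSV.

*Duplex*: global minimum over non-crossing antiparallel inter-strand
pairings (dynamic program over last-pair states with a rectangle-minimum
for loop transitions, O(nm)).  The empty pairing (energy 0) is always
admissible and an MFE of exactly 0 is reported with zero pairs; among
equal-energy pairings more paired bases are preferred, and traceback is
leftmost-deterministic.  The duplex target region is the site plus 30 nt
upstream and 5 nt downstream, enough for full 3′-pairing of the longest
catalog tRF (31 nt) and the position-1 base.

*Local fold*: Zuker-style O(n³) program on the site ±40 nt window
(V = energy given a closing pair, W′ = best with ≥ 1 pair), numba-
compiled.  Accessibility constrains the six site bases unpaired;
opening energy = E(constrained) − E(unconstrained) ≥ 0.  An MFE of 0 is
reported as the open structure — a lone pair at zero energy imposes no
stable constraint and would distort exposure counts.

An optional adapter delegates to the RNAduplex / RNAfold command-line
programs when present; it changes numbers but not the downstream
contracts (MFE ≤ 0, exposure bounds, opening energy ≥ 0), and the test
suite runs entirely on the bundled model.

## Classifier

Stratified fivefold cross-validation (fold sizes within 1, label
proportions within 1 item, deterministic per seed).  Feature selection
is a canonical genetic algorithm over bitmasks: population 50, uniform
crossover applied with probability 0.10, per-bit mutation 0.30,
tournament selection (size 3), one elite, all-zero candidates repaired
by activating a random bit; fitness is the mean held-out AUC of an RBF
SVM over the precomputed folds (the fitness SVM uses the decision
function — rank-equivalent for AUC and several times cheaper than
probability calibration), memoised by mask.  The all-features mask seeds
the initial population, so the returned mask never scores below it.  The
iteration default follows the published setting (10,000); the pipeline,
tests and reproducibility script run 20 generations, which on the
synthetic conditions is past the point where the best mask stops
changing.

Per fold: impute (train medians), scale (train mean/SD), optional inner
grid search over C ∈ {2⁻³…2⁷}, γ ∈ {2⁻⁷…2³}, then an RBF SVM with
sigmoid probability calibration.  A site's probability is the mean of
the five fold models (the five models are the shipped artifact; no final
refit).  Transcript-level aggregation treats sites — including
overlapping ones — as independent: P = 1 − Π(1 − pᵢ), target ⇔ P > 0.5.
The verbal definition of the combined probability (pᵢ = probability a
site is functional) is inconsistent with a bare product — one strong
site would then give a small P — so the noisy-OR complement form is
used; it satisfies P ≥ max pᵢ and the > 0.5 target rule.

Evaluation: sensitivity TP/(TP+FN), specificity TN/(TN+FP), MCC with
NaN (not an error) when a factor of the denominator is zero.  Feature
screening mirrors the training contrast with two-sided Student's
t-tests per feature, positives vs background.

## Probabilistic predictor

The per-position seed-match probability P comes from an order-1 Markov
chain fitted to the tested 3′-UTR itself (empirical initial and
transition frequencies; never-seen source bases fall back to uniform
rows); a pooled-transcriptome background is a config option.  With
n = l − k + 1 positions (k = 6) and f observed matches (overlapping
occurrences all counted, consistent with the scanner),
Ps = upper-tail binomial = `binom.sf(f−1, n, P)`, exact and stable for
large n; f = 0 ⇒ Ps = 1.  Ps values are Benjamini–Hochberg adjusted
over all pairs tested in the run; predictions are ranked by adjusted Ps
and flagged below an FDR cutoff defaulting to 0.05 (the cutoff is a
configurable reporting convenience; ranking is primary).

## Conservation predictor

Per-base scores in [0, 1] are consumed from fixedStep wiggle or bedGraph
files **in transcript coordinates** (genome-to-transcript projection is
out of scope; the synthetic generator emits transcript-space tracks).
Unspecified positions are missing; overlapping blocks and out-of-range
scores are errors.  Each site is summarised by mean score over the seed
region, 35 nt upstream, 15 nt downstream and the whole UTR; prediction
thresholds the **seed-region** mean at 0.5, boundary inclusive, and
sites with zero seed coverage are excluded rather than called.

## Synthetic data generator

Defaults are the study conditions the tests and the reproducibility
script run under: 150 transcripts (3′-UTRs 150–350 nt, CDS 150–400,
5′-UTR 30–120, i.i.d. bases at GC 0.5), 6 tRFs with tRFdb subclass
lengths (tRF-3a 18, tRF-3b 22, tRF-5a 15, tRF-5b 22, tRF-5c 31; tRF-3s
end in CCA), 60 implanted functional pairs and a 5:1 negative sample —
roughly a ninth of the published positive-pair count, sized so the
GA+SVM stage trains in seconds while leaving every per-fold statistic
well-populated.  Functional sites differ from background in exactly
three families: extended complementarity beyond the seed (target gap
`delta_mfe` = 12 kcal/mol, realised as ≈ delta_mfe/2 nt of extra
pairing at 0.75 penetrance under the bundled model's ≈ −2 kcal/mol mean
stack), position-8 complementarity at rate 0.8 (background: 0.25 chance
level), and flank AU fraction 0.75 over ±15 nt (background 0.5).
Neutral seed matches implanted on non-positive transcripts supply the
background; 10 transcripts receive 3 extra matches of one tRF for
enrichment recovery; conservation scores are Beta(8, 2) over implanted
sites and Beta(2, 8) elsewhere; tag counts are uniform on [0, 500).
Fragments for chimeric reads are widened until they occur exactly once
across all UTRs, and site neighbourhoods are redrawn until they hold
exactly one motif occurrence, so read decomposition recovers implanted
pairs exactly — this is what makes 100% recovery a construction
invariant rather than a statistical outcome.

What the generator does **not** emulate: real tRNA cleavage biology,
RNase/ligation biases of CLASH, sequencing errors, isoform structure,
dinucleotide or positional composition of real UTRs, or correlated
features.  Passing tests therefore demonstrate correctness of the
machinery and recoverability of implanted effects, not the accuracy
obtainable on real AGO chimera data.

## Verification strategy

Dynamic programs are checked against independent exhaustive enumeration
(all duplex pairings for strands ≤ 8 nt; all valid structures for
windows ≤ 14 nt), the binomial tail against direct term summation
(1e-12) and Monte-Carlo frequencies (3 SE at 10⁵ draws), the scanner
against a naive sliding window, and the scoring formulas against
hand-derived micro-examples.  The full round trip must reach held-out
AUC ≥ 0.90 with the GA recovering at least two of the three implanted
feature families, while label-permuted AUC stays in [0.45, 0.55] (mean
of 10 permutations).  Family-level recovery is the right granularity
because the AU enrichment informs all three S_AU windows equally — the
GA may keep any of them.

## Known limitations

- The bundled energy model is ordinal, not calorimetric: signs,
  orderings and monotonicities are faithful; absolute kcal/mol are not.
- Only canonical seeds are scanned; G:U, offset and bulged seeds are out
  of scope.
- The background Markov model is order 1; repeat-rich UTRs can inflate
  or deflate Ps.
- Conservation input must already be in transcript coordinates.
- Multi-mapping fragments are kept by default; with highly repetitive
  UTRomes this can duplicate positives across paralogous transcripts.
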