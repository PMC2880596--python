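# Methods

## Library model and extraction conventions

A nucleosome library is a list of 147-bp sequences over {A,C,G,T,N,X} with
positive integer read weights.  Coordinates in input tables are 1-based
inclusive; a dialect config handles 0-based input, column layouts, and
strand symbols.  Two coordinate conventions are supported:

* **5′ end** (strand-directed): `+` reads give `genome[coord .. coord+146]`,
  `-` reads the reverse complement of `genome[coord-146 .. coord]`.
* **midpoint**: `genome[coord-73 .. coord+73]`, strand applied afterwards.

Both place the dyad at library position 74 (dyad-relative coordinates
−73..+73), so all downstream statistics share one frame.  Records whose
window would leave the chromosome are dropped and counted, never clipped:
a partial window would corrupt position-resolved counts.  Sequence
ambiguity (N) is retained; any motif window containing N (or the masking
symbol X) matches nothing.

All strand-symmetric statistics are computed on the reverse-complement
closed library (every sequence plus its reverse complement, weights
copied), or equivalently with a motif counted together with its reverse
complement.

## Counting convention

A motif of length L starting at 1-based position s is tallied at
`s + floor((L-1)/2)`.  This single rule makes the centers of all
odd-length motifs coincide and counts an even-length motif at the first
base of its central dinucleotide, so CTAG at s and its central TA step at
s+1 land on the same position.  The absolute dyad-relative phase of this
convention could legitimately differ by one bp from alternatives (count at
the 3' central base); the phase-angle reference absorbs such an offset, and
the generator reports ground-truth phases *through the same definition*
(see below), so recovery statements are convention-independent.

Counting is weighted: a sequence with w reads contributes w per
occurrence, treating read depth as a proxy for octamer affinity.  The
weighted-counting contract (weight w equals w duplicated copies) is
enforced by test for profiles and whole statistic tables.

Isolated homopolymer runs (the A/T-tract analysis) are exact-length runs
whose immediate 5′ and 3′ neighbors both lie in the flanking class S =
{C,G}; flanking by A or T disqualifies (this excludes AATT/TTAA/ATTA-type
composites from the tract signal), and runs touching the window edge are
discarded because a flank cannot be verified.

## Spectral statistics

The transform is a direct DFT on the non-uniform period grid `c/h`,
`c = 2000`, integer `h = 150..250` (13.33 down to 8.0 bp; `h = 196` is
10.2 bp), over the window x = 3..144 (142 positions — positions that every
motif length up to 4 can populate; the same fixed window is used for all
lengths for comparability).  The window mean is subtracted, so a flat
profile has an identically zero spectrum.  Smoothing (three-bond average)
exists for display and serialization only; spectra always consume raw
counts.

* `FVO_h = 2|C_h| / (142 fbar)`.  The scaling is fixed by the calibration
  requirement that a pure cosine of fractional amplitude a at a matched
  period return FVO = a; spectral leakage bounds the calibration error
  below 1% of a, which the tests assert at a = 0.10 (+/-0.001).
* `%FTS_10.2` integrates amplitude (not power) over the harmonics whose
  period falls in 9.8..10.6 bp (h = 189..204, 16 of 101 bins) relative to
  the whole grid.  Unstructured noise therefore scores ~16%; the
  significance threshold used for tetranucleotide selection is 19%.
* Phase angle: `theta = arg(C_196) + 360 * 196 * 2 / 2000` degrees, wrapped
  to (-180, 180].  The additive term references position 2 (dyad-relative
  -72): profiles with maxima at -72, -61.8, ... read 0 deg.  The position-2
  reference is not a mirror fixed point of the 147-bp frame, so a
  reverse-complement pair's phases are opposite only up to a systematic
  ~5 deg offset, and a pair-summed profile reads ~ -2.5 or ~ +177.5 deg
  rather than exactly 0/180 — a known property of this reference choice,
  asserted as such in the tests.
* Ties in the maximal-amplitude period are broken toward h = 196, so a
  degenerate all-zero spectrum reports the 10.2-bp bin with FVO 0.
* Zero-count profiles propagate as FVO 0 with NaN phase; mean-FVO
  aggregates count them as 0 (they carry no signal).  Division by a zero
  mean is never performed.

## Consensus groups, selection, masking

The eight consensus groups ship as IUPAC patterns (YTAR, WTAW, YCAG+CTGR,
RCAY+RTGY, RACY+RGTY, RCGY, RGCY) plus an explicit A-run/T-run family
(AnTm) expanded as all {A,T}-only tetramers without a TA step
(AAAA, AAAT, AATT, ATTT, TTTT).  Closed under reverse complement the
defaults comprise 40 literal tetranucleotides, 24 unique — the group
definitions are an editable config, and double matches (e.g. TTAA is both
YTAR and WTAW) resolve by a fixed priority order with YTAR before WTAW.

Selection of periodic tetranucleotides uses three filters: FVO_10.2 no
more than half an SD below the 256-tetramer mean, %FTS_10.2 > 19, and a
phase angle in the minor-groove-in (|theta| > 135 deg) or -out
(|theta| < 45 deg) window; specific tetranucleotides can be force-included.
Distribution classification (peripheral/central/uniform) compares mean
normalized occupancy over dyad+/-30 against the outer thirds with a 1.15
ratio cut — thresholds are plumbing defaults, configurable.

Masking replaces bases with X.  "Consensus only" keeps exactly the
positions covered by at least one (possibly overlapping) member
occurrence on either strand; "no consensus" is the exact set complement,
so the X-positions of the two modes partition every sequence (tested), and
member words have zero occurrences in the no-consensus library.

## The synthetic generator

Backgrounds are i.i.d. bases at a configurable GC content (default 0.39,
the S. cerevisiae genome value).  Each planted motif receives
Poisson(lambda) insertions per sequence at start positions drawn from
`p(s) ∝ 1 + a cos(2π(s - x0)/P)`; insertions overwrite the background
(preserving the 147-bp frame) and footprints never overlap — collisions
are resolved by bounded rejection sampling, and configurations too dense
to place are rejected up front.  Read counts come from one of three
models: constant, geometric, or affinity-coupled
(`reads = 1 + Poisson(base + gain * insertions)`), the last emulating the
enrichment of high-affinity sequences among highly-read fragments.

Ground truth records every insertion, the read draws, and per-motif true
period/phase/amplitude; the "true phase" is obtained by pushing the
infinitely-sampled ideal profile through the same phase definition the
analysis uses.  Generation is vectorized across sequences from seeded
child streams (background / per-motif placement / reads) of a single root
seed; identical seeds give byte-identical libraries.  A per-sequence
counter-based substream design was considered and rejected: it costs two
orders of magnitude in generation speed and buys nothing observable, since
order-independence across parallel workers is not a use case here.

What the generator does *not* emulate: MNase digestion bias and fragment-
length heterogeneity, genomic composition structure (isochores, repeats),
linker-length constraints, and nucleosome-nucleosome phasing.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated statistical model, not performance on real chromatin data.

One intrinsic artifact of insertion-style planting deserves note: because
insertions overwrite background at position-modulated sites, every
*non-planted* motif acquires a compensating anti-phase modulation of its
background occurrences, with aggregate magnitude comparable to the planted
signal when many motifs are planted at a common phase.  Real libraries do
not show this, because their periodic elements interleave at opposite
rotational phases (minor-groove-in vs -out, half a helical turn apart),
keeping total occupancy nearly uniform.  Decomposition experiments on
synthetic data therefore plant balanced in/out sets — the package's
ground-truth masking study uses one "in" reverse-complement pair
(CTAA/TTAG) and one "out" pair (GCAC/GTGC) planted half a period apart at
amplitude 0.3 and lambda = 3 per pair, n = 200,000 sequences.  Problem
sizes for recovery studies (n = 20,000) and the masking study (n =
200,000) were set by a noise floor analysis: the mean noise FVO of a
tetramer scales as sqrt(pi/(142 mu)) with mu counts per position, and n is
chosen so this floor sits well below the planted effect being measured.

## Numerical and degenerate-input choices

* Period reported as c/h of the argmax bin; display rounding 0.01 bp.
* Phase wrap maps -180 to +180 (principal interval (-180, 180]).
* Empty sub-libraries in read stratification report missing values (NaN),
  not zero.
* Phase adjustment (probe AAAA counted with its reverse complement,
  target +/-180 deg, shift magnitude 5 bp) picks the shift direction that
  minimizes the residual misphase, trims the shifted end and pads with N,
  and records the applied shift in library metadata; libraries already
  within tolerance (45 deg) pass through unshifted.
* Cross-library summaries exclude tetramers by the half-SD rules (FVO_MAX
  for period averages, FVO_10.2 for phase correlations, applied in both
  libraries for the latter) and report NaN correlations when fewer than 3
  shared tetramers survive; "mean tetra FVO" averages all 256 tetramers,
  not the 136 unique ones (a canonical-only view is a one-line pandas
  filter on the stats table).
* Pearson correlations return NaN on constant input instead of warning.

## Known limitations

* The fragment-67 panel ships with the published octamer-level FVO column;
  centered hexamer/tetramer/dimer FVOs are recomputed from whatever
  library is supplied, so panel correlations at those lengths depend on
  the library used.
* Isolated-run counting is restricted to homopolymer A/T runs with a
  single flank class, the only case the A-tract analyses need.
* Phase correlation across libraries is a linear Pearson on angles in
  degrees (the field's convention for this comparison), which is adequate
  because retained phases cluster near 0/±180 but is not a circular
  correlation statistic.
* The consensus member list is generated from the group patterns; users
  comparing against a hand-curated list can override membership in the
  group config.
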