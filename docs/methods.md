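# Methods

This note documents the models and procedures implemented in `pymocca`,
the defaults and the reasoning behind them, what the synthetic benchmark
does and does not demonstrate, and the numerical conventions that fix
otherwise ambiguous behaviour.

## Sequences and background models

Sequences are handled as upper-case strings over {A,C,G,T,N}. Degenerate
IUPAC letters in *input sequences* are conservatively collapsed to N with a
warning; N never matches any motif position, so ambiguous bases can only
remove, never add, occurrences.

Background models are order-N Markov chains fitted by add-one-smoothed
relative frequencies of (N+1)-mers; windows containing N are skipped, and
the initial-context distribution is the smoothed empirical N-mer frequency.
Add-one smoothing guarantees every context can emit every base, so
generation can never lock up; order 0 degenerates to an i.i.d. nucleotide
model. Generation is a pure function of (model, count, length, seed).

## Motif scanning

**IUPAC motifs** (optional Hamming mismatch budget 0–2) are compiled
together into one deterministic finite automaton by lazy subset
construction over partial-match items (pattern, position, mismatches-used);
scanning is a single pass with one table lookup per base, independent of
the number of motifs. Reverse-strand matching compiles the
reverse-complemented pattern alongside; a motif equal to its own reverse
complement is compiled once and reported on '+' only (one occurrence per
site). Overlapping occurrences of the same motif are all reported — the
pair and frequency features are defined on this convention. A sequence N
kills every partial match outright: a window containing N never matches,
even when mismatch budget remains. The mismatch cap of 2 bounds the state
count.

**PWM motifs** are parsed from horizontal PSSM text (four labelled rows of
counts per record), pseudocount-smoothed (default 1.0), column-normalised
and log-odds-transformed against a background distribution (default
uniform 0.25, both configurable). An occurrence is any offset, on either
strand, whose summed log-odds reaches the motif's threshold; windows
containing N are skipped. The reverse strand is scored with the
row-reversed, column-reversed matrix in forward coordinates.

**Threshold calibration** targets an expected occurrence rate per kilobase:
a 1 Mb (default) i.i.d. background is simulated, all windows on both
strands are scored, and the threshold is the empirical score quantile at
which round(rate × length/1000) windows score at or above it. Discrete PWM
score distributions produce tie blocks at the quantile; the implementation
takes the side of the tie block whose count is closer to the target.
Calibration is empirical rather than analytic (no dynamic-programming score
distribution) — minimal assumptions, at the cost of simulation time. Note
that the realised rate on fresh background is exact only in expectation;
self-overlapping (repeat-like) motifs clump their occurrences, which
inflates the variance of a rescan count well beyond binomial.

## Feature spaces

All coordinates are 0-based half-open; an occurrence belongs to a window
iff its start lies in the window (unambiguous at borders). Pair distances
are centre-to-centre; the default pair cutoff of 219 bp is the classic
pairing window of log-odds PRE predictors and is exposed, not hard-coded.
Self-pairs are included (homotypic clusters carry signal) but an occurrence
never pairs with itself, and each unordered occurrence pair counts once.
The distance-binned variant stratifies pairs into [0,b), [b,2b), … with the
final bin closed at the cutoff. Frequency-type spaces are per-kilobase
normalised by default so that clipped or variable-length windows remain
comparable; dinucleotide frequencies and GC content are fractions over
N-free positions. Feature name order is deterministic (sorted motif names;
pairs as sorted unordered names) so that fitted weights are portable.

## Base models

* **Unweighted sum** — the plain sum of feature values; with pair features
  this is the Dummy PREdictor.
* **Log-odds** — w_f = ln(mean_pos(f)+p) − ln(mean_neg(f)+p) over class
  means of per-kilobase feature values, pseudocount p = 0.1 (configurable);
  score = Σ_f x_f w_f. The difference-of-logs form makes swapping the
  classes negate every weight bit-exactly. Class means of per-kb values
  (rather than pooled counts) keep sets of unequal sequence lengths
  comparable; the pseudocount guarantees finite weights. With pair features
  this is the CPREdictor.
* **SVM** — standardized features, one-vs-one multi-class, quadratic
  polynomial kernel (degree 2, coef0 1) by default with C = 1 and balanced
  class weights; linear and RBF kernels available. The ranking score is the
  signed distance (binary) or the positive class's aggregated margin minus
  the best rival's (multi-class).
* **Random forest** — 300 trees by default, unlimited depth, √(features)
  per split, deterministic given the seed; the ranking score is the
  positive-class vote fraction.

A training matrix whose rows are all identical is rejected (with the
constant features named); individually constant columns are tolerated —
they arise routinely in local-window features — and contribute nothing
after standardization.

## Hierarchical models (SVM-MOCCA / RF-MOCCA)

One multi-class classifier per motif is trained on the local landscape of
every occurrence of that motif: a window of W = 500 bp (even, configurable)
centred at the occurrence, clipped at sequence ends, described by local
motif occurrence frequencies (per kb of the actual clipped window,
including the anchoring occurrence), dinucleotide frequencies and GC
content, each toggleable. An occurrence is "positive" when the classifier's
arg-max class equals the designated positive class. Per sequence, the
per-kilobase counts of positive-classified occurrences per motif feed a
log-odds combination layer, fitted positives versus the pooled negative
classes. A sequence without occurrences scores exactly 0 (empty count
vector under a linear model). Motifs with fewer than 5 training occurrences
in any class (floor configurable) are dropped from per-motif modelling with
a warning — their classifiers would be unfittable — but still count in the
local motif-frequency features.

Two documented degrees of freedom: the combination layer uses per-kilobase
(not raw) positive counts, giving sequence-length invariance, and negatives
are pooled (not modelled per class) in the combination. Forcing every
per-motif classifier positive makes the model collapse exactly onto a plain
log-odds model over motif frequencies; this identity is tested.

**Core-CRE prediction.** Within a positive window, occurrences are
classified once; candidates are [start(a)−P, end(b)+P) for every pair
a < b of positive-classified occurrences plus [centre−P, centre+P) for
every single one, with P = W/2 = 250 bp, clipped to the window and
deduplicated after clipping. Each candidate is scored by the combination
layer on its per-kb positive counts; the candidate maximising score/length
wins, ties broken towards the shorter, then leftmost interval (so the
result is unique and order-independent). The score-per-base-pair
denominator is the clipped interval length. With no positive occurrence the
whole window is returned, flagged.

## Prediction, calibration and validation

Sliding windows tile [0, L) at the given step with a flush-right tail
window appended when the last regular window falls short of L; sequences
shorter than the window yield one clipped window. Windows scoring at or
above the threshold are emitted; overlapping or adjacent positive windows
merge into one prediction carrying the maximum member score (configurable
to mean). For the hierarchical models, occurrences are scanned and
classified once per chromosome and windows are scored from cumulative
counts, not by rescoring subsequences.

Threshold calibration for a target expected precision q scans the observed
scores and returns the smallest threshold t with
TP(t) / (TP(t) + w·FP(t)) ≥ q, where w up-weights the calibration
negatives to genome scale (in auto mode, w = genome length / total
calibration-negative length). An unattainable q returns a threshold above
every observed score, with a warning.

PRC AUC is computed as average precision — the step-wise sum
Σ (R_i − R_{i−1}) P_i — deliberately avoiding the optimism of trapezoidal
interpolation in PR space; ROC AUC is the Mann-Whitney statistic with ties
averaged. Both agree with brute-force all-threshold enumeration (tested).
Cross-validation draws disjoint train/test splits per repeat from one seed
sequence and reports means with t-distribution 95% intervals (repeats are
few, so a normal interval would be anti-conservative).

## Auto mode

The pipeline requires ≥ 20 positives (floor configurable): split 70/30 by
whole sequences (never windows, to prevent leakage); fit an order-4 Markov
model on the genome (order 4 captures local composition without excessive
table size; configurable) and generate dummy-genomic negatives matched in
count and length distribution to the positives; build dummy-CRE negatives
by re-planting each positive's per-motif occurrence counts at uniform
positions in fresh background; train the requested model (default
RF-MOCCA; the two-class presets train on positives versus dummy-CREs,
multi-class models on all three classes); validate on the held-out split;
calibrate the threshold to a default precision target of 0.8; scan the
genome. One master seed fans out into independent stage seeds through a
seed-sequence spawn, so every artifact is reproducible from the resolved
config snapshot plus the master seed, and outputs are byte-identical across
reruns.

## The synthetic benchmark: what it shows and what it does not

The planted-CRE generator emulates the classic training design for PRE-type
classifiers: positives carry fixed per-motif instance counts placed inside
a randomly positioned cluster window (default 500 bp within 2 kb), dummy-CRE
negatives carry identical marginal counts placed uniformly (destroying
clustering and pairing), and dummy-genomic negatives are pure background.
Motif instances are concrete realisations of the degenerate pattern (or
PWM column distribution), planted without mutual overlap, on a random
strand. The defaults used throughout the tests — 2 kb sequences, 5+5
planted instances of two 5-bp motifs, uniform i.i.d. background — make
motif frequency uninformative between positives and dummy-CREs by
construction, so any separation measured there is combinatorics signal.

This is a deliberately idealised world: real CREs differ from real genomes
in composition (the background here is what the negatives were generated
from), motif instances in vivo are degenerate and context-dependent, real
negatives are heterogeneous (e.g. coding sequence, which the generator does
not emulate — such sets are supplied by the user as FASTA), and genuine
positive sets are small and noisy. Passing tests therefore demonstrate
correctness of the machinery and the *direction* of the hierarchical
models' advantage on combinatorially structured data, not expected
performance levels on any real genome. Test problem sizes (60 training
sequences per class, 10 repeats, 200 kb genomes with 30 planted CREs) are
chosen as the smallest scales at which these directional effects are
stable across seeds.

## Known limitations

* No analytic PWM p-values, no motif discovery, no MEME/JASPAR parsing.
* IUPAC mismatch budgets above 2 are rejected (FSM state growth).
* The per-motif classifiers are not probability-calibrated; combination
  inputs are hard arg-max decisions.
* LDA and averaged-perceptron base models are not provided.
* Genome scans are single-threaded; the hierarchical models classify every
  occurrence and are correspondingly slower than the log-odds presets.
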