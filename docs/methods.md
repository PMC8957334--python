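# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `neurosep`.

## Stimulus design

The design crosses 8 character glyphs with 6 retinal slots and 4 distortion
levels.  Slots are abstract positions 0.8° apart; slots 1–3 carry the
ipsilateral label and 4–6 the contralateral label (the labels, not physical
laterality, are what every operation uses).  Single letters occupy every
slot (48 placements); n-grams of length 2–6 occupy the canonical contiguous
run — even lengths centred on fixation, odd lengths with the extra letter
contralateral.  The default easy set is (48 + 50) × 4 = 392 descriptors.

**Default n-gram strings.**  The 10 strings per length are built as ten
*nested chains*: ten distinct seed bigrams are drawn (seeded RNG) and each
is grown one random glyph at a time — prepended or appended — up to length
6, rejecting growth steps that would create one of the other seed bigrams.
Each length-m chain member therefore occurs contiguously inside every
longer member of its chain, while containment of the ten bigram types stays
selective (a given bigram is carried by its own chain, not by every long
string).  This nesting is what the conjunction error analysis exploits, and
its selectivity is what gives that analysis statistical power; a
maximally-overlapping construction (e.g. all circular windows of one glyph
ordering) makes every 6-gram contain most bigram types and washes the
analysis out.  Any explicit string list can be supplied instead.

**Rendering** is optional — all analyses operate on symbolic descriptors.
Glyphs are drawn in a serif face and auto-scaled per glyph so every ink
bounding box is ≈0.8° tall.  The fish-eye is a bounded spherize lens:
inside lens radius L (half the canvas), the output at radius r samples the
source at `L·(r/L)^(1+k)` (lens exponent k = 0.10 by default), which
magnifies the centre, compresses toward the rim, is the identity outside,
and conserves foreground ink to ~10 %.  Level 2 adds an independent
uniform(−15°, 15°) in-place rotation per glyph; level 3 additionally bends
glyph baselines along one of two quadratic arcs (sagitta 0.4 glyph heights).
Hard variants: touching (rotated glyphs packed until bounding boxes abut),
outline (ink minus its binary erosion), grid and strike-through (level-2
rendering composited by pixelwise maximum with a line grid or a wavy
stroke).  Glyph geometry is deliberately not load-bearing for any analysis.

## String bank

For each length n, the base pool is all 8ⁿ ordered glyph sequences at the
canonical slots (repeats allowed: 64 bigrams … 262,144 6-grams).  The pool
is closed under 6-slot circular rotation and order-preserving
redistribution of letters over the slots (iterated to a fixed point, so
expansion is idempotent); gapped strings such as `*a**b*` are legal
everywhere downstream.  A bank stimulus is a (pattern, distortion-level)
pair: the pattern pool for bigrams has a hard combinatorial ceiling of
C(6,2) × 64 = 960, so only the pattern × distortion product (3,840) can
support the default balanced size of 3,584 per length (5 × 3,584 = 17,920
stimuli total).  Sampling is uniform without replacement, per length,
seeded.

## Synthetic populations

Each separable neuron has marginal tuning vectors for shape (8), location
(6) and distortion (4), all in [0, 1]:

- *sharp* — one-hot per factor;
- *broad* — i.i.d. uniform(0, 1);
- *mixed* — Bernoulli(1/k) mask × uniform values, k drawn uniformly from
  {1…6} per neuron (masks are redrawn until at least one entry survives,
  since a dead factor would silence the neuron entirely).

A neuron is sharp (or broad) for all three factors jointly.  The `mixed`
population policy assigns sharp or broad with probability ½ each; the
`all-mixed` policy uses the sparse tuning above.

Per-slot letter response: `S_i × P_j × D_k` (multiplicative) or
`(S_i + P_j + D_k)/3` (additive; the ÷3 keeps the two rules on comparable
scales — correlation- and decoding-based comparisons are insensitive to
it).  String response: sum or product over occupied slots, divided by the
string length when divisive normalization is on (a no-op for single
letters).  The gain (spikes/s, default drawn uniform(20, 80)) multiplies
the combined string response exactly once, so responses scale linearly
with gain under both string rules — this is what makes the reliability
matching below a monotone one-dimensional search, and it is the only
well-behaved convention for the product rule (a per-slot gain would scale
n-gram responses as gainⁿ).

**Conjunction controls.**  Type 1 responds at full gain when its preferred
bigram occupies two adjacent slots in order, and not at all otherwise
(including all single letters).  Type 2 adds a baseline equal to 30 % of
the neuron's reference mean rate on every other stimulus ("mean" is read
as the across-stimulus mean; absent an external reference the gain itself
serves as the reference scale).  Type 3 is compositional — a
divisively-normalized sum of uniform(0,1) letter-by-slot terms — except
that when the preferred bigram is present its two letters are replaced by
a single deviant term drawn uniform(0, 1) × 8.  The ×8 scale makes the
conjunction the neuron's dominant drive (mean 4.0 versus a mean
whole-string letter sum of 3.0), consistent with types 1–2 whose preferred
bigram elicits the maximal response; a small deviant term is provably
undetectable here because the compositional model's denoising gain (mean
cv − reliability ≈ +0.17 at reliability 0.5) swamps it.  Preferred bigrams
cycle through the ten bigram types of the stimulus set in use.

**Noise and reliability.**  Spike counts are Poisson with mean
rate × 0.15 s (the 50–200 ms window), independent across neurons, stimuli
and repetitions; stored responses are counts/window in spikes/s, 4
repetitions by default.  Repetitions are numbered from 1; the odd half is
reps 1, 3 and the even half reps 2, 4.  `match_reliability` runs a
vectorized bisection on log-gain (18 iterations over gain ∈ [10⁻², 10⁵]),
scoring each probe by the mean split-half correlation over 20 Monte-Carlo
samplings of the stimulus set under consideration.  Matching is always done
on the stimulus subset the analysis will use (letters for factor fits,
n-grams for composition fits): reliability is defined across the stimuli
under consideration, and matching on a pooled set lets whichever subset
has the larger dynamic range dominate, leaving the other effectively
unconstrained.  Neurons with stimulus-constant expected rates can never
reach a positive target and are flagged unreachable (gain left unchanged).

## Separability models

**Reliability.**  Per neuron, Pearson correlation between odd- and
even-repetition mean rates across the analysis stimuli.  NaN (constant
half) and negative values are masked out of population summaries, but
individual fits are still produced.

**Factor models.**  Marginals are estimated on the training half by
averaging over the other factors (e.g. shape tuning = mean response to
each glyph across locations and distortions); the prediction is their sum
or product over the included factors, affinely rescaled (least-squares
slope + intercept) to the training half — correlation-based evaluation is
affine-invariant, so the rescale only stabilizes reported predictions (a
min–max alternative was considered and rejected as strictly less stable).
The cross-validated correlation averages the train-odd/test-even and
train-even/test-odd directions.  Reduced models use factor subsets;
lateralized fits restrict the slots.  The full model has 8 + 6 + 4 = 18
marginals predicting 192 conditions.  The combination model regresses the
training half on (r_a, r_m, r_a·r_m) plus an intercept by least squares
(minimum-norm when collinear, flagged).

**N-gram composition.**  Letter regressors default to the multiplicative
factor model's predicted letter grid (clipped at zero); raw letter means
are a config alternative.  The denoised predictions matter: raw letter
means inject per-letter estimation noise into every string containing that
letter, which correlates model errors across strings that share letters
and can masquerade as conjunction structure.  The additive model stacks
all 200 conditions into one system with per-length blocks (n letter
columns + 1 constant: 25 columns), solved by least squares on the training
half; the composite cross-validated correlation pools all 200 held-out
conditions.  The multiplicative model is fitted per length in log space
(`log(y + ε)` on `log(X + ε)` + constant), predictions are
exponentiated (hence strictly positive) and pooled.  ε defaults to 1 % of
the neuron's maximum training-half rate.  The string × distortion model is
the two-factor (50 + 4 marginals) version of the factor fit.

**Shuffle control.**  Condition labels are permuted over all n-gram
conditions, independently for the odd and even halves.  Both choices are
deliberate: a within-length permutation can never null the per-length mean
structure that the per-length constant columns legitimately fit, and a
single shared permutation leaves the training-half overfit (~25/200 of the
variance) intact in the identical held-out half — either way a
"compositional" correlation of 0.15–0.40 survives on noise-free separable
data.  With global, per-half permutations the control collapses to ≈0 as
a null control must.  An explicit permutation argument (applied to both
halves) is available; identity reproduces the unshuffled fit exactly.

## Decoding

The 8-way letter decoder uses repeated stratified 80/20 splits; the
per-slot decoder trains six 9-way classifiers (8 letters + blank).  Per
slot, blanks are subsampled to the rounded mean letter-class count (blanks
dominate eccentric slots, and an unbalanced classifier wins by answering
"blank"); classes with fewer members than folds are dropped at that slot.
Features are reduced by PCA fit on the training fold only, keeping the
smallest number of components reaching 95 % cumulative variance (the
feature matrix is divided by its maximum absolute value first — this
leaves explained-variance ratios unchanged and avoids LAPACK convergence
failures on the wide dynamic ranges sparse populations produce; a
randomized-SVD fallback covers the remaining failures).  The default
classifier is multinomial logistic regression on standardized inputs
(training statistics only); a shrinkage linear discriminant is the config
alternative.  The logistic default is a deliberate choice: with identical
features, balancing and PCA, shrinkage-LDA plateaus around 98.8 % on the
best separable configuration whereas the logistic decoder reaches the
near-perfect accuracy the separable code actually supports.  Folds with no
informative feature fall back to the majority class, so all-zero
populations (sharp multiplicative tuning can silence entire stimuli)
report degraded accuracy rather than erroring.

For shuffle controls the per-slot decoder offers a balanced-accuracy
metric (mean per-class recall): slot classes are inherently unbalanced —
eccentric slots are mostly blank, interior slots never are, and not every
letter occurs at every slot in a 50-string design — so plain accuracy has
a no-information rate well above the nominal 1/9.  Balanced accuracy's
no-information value is 1/(classes present), and the decoder reports this
empirical chance (mean over slots of 1/classes-trained) next to the
nominal level.  Shuffle nulls are averaged over several independent label
permutations, since any single permutation carries a few percent of
dataset-level luck through the letter-placement feature clusters.

`compare_population_decoders` evaluates noise-free expected-rate features
for a grid of simulator settings on a balanced bank; the study-scale
reduction used throughout the tests and the acceptance script is 1,000
neurons on 500 strings per length, which preserves every qualitative
ordering of the full-scale configuration at a few minutes of compute.

A note on the sharp-tuning/normalization ordering: divisive normalization
hurts decoding only for populations whose string response is carried by
few slots — sharp *multiplicative* neurons, whose response to a string
containing their trigger is constant without normalization but
length-dependent with it.  Sharp *additive* neurons respond at every slot
(the additive rule has no zero product), their summed response grows with
string length, and normalization stabilizes it — the ordering genuinely
reverses, so the sharp-tuning claim is evaluated on the multiplicative
cells where the mechanism operates.

## Conjunction error analysis

The compositional (letter-sum) model is fitted to the all-trials mean
response after normalizing each neuron to its maximum rate (neurons with
zero maximum are masked); the table of absolute errors is therefore
invariant to global rate rescaling.  Containment means the shorter
string's letters occupy consecutive slots of the longer string.  Per
neuron, base n-grams are median-split by error (ties to the low group);
for each longer length, the mean error of strings containing at least one
high-error base is compared with that of strings containing a low-error
base, and a two-sided Wilcoxon signed-rank test is run across neurons.
The grouping criterion uses different stimuli than the compared quantity,
so no cross-validation is needed.  A membership-shuffle option permutes
which longer strings contain which bases, destroying genuine conjunction
signals.

## What the generator does and does not emulate

The generator reproduces the study conditions that the analyses are
sensitive to: the exact combinatorial design, marginal-tuning families,
additive/multiplicative composition, divisive normalization, Poisson
repetition noise, and reliability matching.  It does not model temporal
structure (latencies, PSTHs), correlated noise across neurons or
repetitions, adaptation across the trial sequence, or the tuning
correlations of real IT neurons.  Passing recovery tests therefore shows
the *analyses* are correct and well-powered under these idealized
conditions — not that real cortex is separable.

## Known limitations

- The generalized-product (log-linear) n-gram model's advantage on
  product-generated strings is erased by Poisson noise at reliability 0.5:
  the log transform amplifies letter-regressor noise exactly where product
  responses are small.  The reversal is clean in the noise-free limit
  (property-tested) but not statistically detectable at 100 neurons under
  noise; the analysis reports it honestly rather than detecting it.
- Reliability matching assumes response ∝ gain, which the generator
  guarantees; matching ingested data with other noise models would need a
  different search.
- The CSV ingestion path accepts any tidy rate table whose stimulus ids
  resolve against a manifest; it does not parse any external deposit
  format directly.
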