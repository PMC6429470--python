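# Methods

## Sequence model and scope

All features operate on the primary sequence over the 20 standard
amino-acid one-letter codes. Ambiguity codes (B, Z, X, J, U, O) are
rejected at parse time — every encoding below is defined only on the
standard alphabet — with an option to drop offending records instead.
Dataset curation (e.g. removing proteins shorter than 80 residues, as
is common for these benchmarks) is exposed as an explicit filter
(`filter_min_length`, CLI `--min-length`) defaulting to no filtering.

## Reduced alphabets

Two fixed many-to-one groupings:

| six-letter | members | three-letter | members |
|---|---|---|---|
| H | H R D E N Q K | F (internal) | F I L M V |
| L | L I V A M F | D (external) | D E H K N Q R |
| S | S T Y W | S (ambivalent) | S T Y C W G P A |
| P / G / C | themselves | | |

Both tables are asserted at import time to partition the 20 codes.
The three-letter group names collide with amino-acid letters, so
encoded sequences are distinct types and are never re-encoded.

## GCGR: hexagonal chaos-game walk

Geometry: a regular hexagon with unit edge length, which for a regular
hexagon equals the circumradius. The package places the center at the
origin and assigns vertices H, L, S, P, G, C counter-clockwise at
angles 0°, 60°, …, 300°, H at (1, 0). The walk starts at the center
(regardless of the first letter) and each subsequent point is the
midpoint of the previous point and the current letter's vertex. The
feature pair is the coordinate mean (x̄, ȳ) of all points; the summary
statistic is pluggable (median, percentiles) but only the mean is used
by the shipped models.

The absolute vertex placement is a convention: any rigid motion of the
hexagon moves every feature by the same rigid motion, which leaves the
nearest-centroid decision and the (scaled) SVM unchanged. The
translation equivariance and center-invariance of pairwise feature
distances are property-tested. Consequences: absolute x̄/ȳ values are
convention-dependent and only geometry-invariant quantities are
comparable across implementations. Coordinates are kept at full float64
precision; no rounding occurs during the walk.

Two useful exact properties (both tested): every walk point stays in
the closed hexagon (midpoints of a convex set), and during a
constant-letter run the distance to that letter's vertex halves at
every step, so long homogeneous stretches pull x̄ toward "their"
vertex geometrically fast.

## NSI: interval statistics

For each reduced letter k ∈ {F, D, S}: W(k) is the ordered list of
1-based occurrence positions (the three lists partition 1..L), and
N(k) the consecutive differences of W(k) — m occurrences give m − 1
intervals, with no cyclic wrap-around term. Treating the interval as a
discrete random variable x with empirical pmf p(x):

    E(k) = Σ x·p(x),    D(k) = E(x²) − E(x)²,    I(k) = E(k)/D(k).

The variance is the population form (no Bessel correction). I(k) is
the reciprocal index of dispersion: large for clock-like recurrence,
small for bursty placement. When D(k) = 0 — the letter occurs fewer
than three times, or at perfectly constant spacing — I(k) is undefined
and a sentinel value is reported, 0 by default and configurable. The
sentinel keeps feature vectors finite; zero was chosen because it is
maximally distinct from the large I(k) of genuinely regular spacing,
but note it conflates "absent" with "perfectly periodic", a known
limitation for very short or highly repetitive sequences.

## Classic views

Dipeptide composition: frequencies of the 400 ordered adjacent pairs
among the L − 1 overlapping pairs; sums to 1.

PseAAC (Chou type I): 20 residue frequencies plus λ sequence-order
correlation factors θ_j, each θ_j the average over residue pairs at
distance j of the mean squared difference of three standardized
physicochemical scales (hydrophobicity, Hopp–Woods hydrophilicity,
side-chain mass; each standardized to zero mean and unit population
variance over the 20 residues). All 20 + λ components share the
normalization p_u = f_u/(Σf + wΣθ) (u ≤ 20), p_u = wθ_{u−20}/(Σf + wΣθ),
so the vector sums to 1. Defaults λ = 20, w = 0.05 — the
community-standard settings; both are exposed through the API and CLI.
Sequences must be longer than λ.

## Parallel complex fusion and the unitary distance

The GCGR pair u (2-D) and NSI triple v (3-D) are combined as one
complex vector z = u + v·i in C^m, m = max(dim u, dim v). The shorter
vector is right-padded; the default "ratio" rule appends the scalar
x̄/ȳ (undefined and rejected when ȳ = 0), the alternative "alternate"
rule appends x̄, ȳ, x̄, … cyclically. Both readings are shipped
because the padding phrase that motivates them is ambiguous; the
choice only affects the third real component of a 3-D vector and both
rules are covered by tests.

The unitary norm is ‖z‖ = √(Σ aₖ² + bₖ²), i.e. the Euclidean norm of
the stacked real/imaginary 2m-vector, and the unitary distance is
‖z₁ − z₂‖ — a genuine metric (property-tested). It is symmetric in
which view is real and which imaginary, so the u/v assignment cannot
affect predictions (asserted).

The classifier-free predictor is nearest class centroid under this
distance — the simplest decision rule consistent with a
"classifier-free" model; 1-nearest-neighbor is available as a config
option. Ties are broken deterministically by class order. Centroid
models serialize to versioned JSON.

## Multi-view SVM

Fusion vector: GCGR(2) ‖ NSI(3) ‖ PseAAC(20+λ) ‖ dipeptide(400), 445-D
at λ = 20, with stable unique feature names. Classifier:
`sklearn.svm.SVC` (libsvm) with RBF kernel exp(−g‖x−y‖²), one-vs-one
multi-class, cost c and gamma g.

Feature scaling: per-feature min–max to [0, 1], learned from the
training rows only (inside each jackknife fold — the held-out sample
never touches the scaler; this is asserted by recomputing folds by
hand in the tests). Range scaling is libsvm's `svm-scale` convention
and the package default for a concrete numerical reason: the raw views
differ by orders of magnitude (dipeptide entries ~10⁻², I(k) up to
tens), so *some* scaling is mandatory, but z-scoring 445 features
pushes typical squared distances to the several-hundred range where
exp(−g·d²) underflows for every g in the default grid; the kernel
matrix then degenerates toward the identity and leave-one-out
prediction collapses to the training majority class. Under [0, 1]
scaling the default grid spans the useful kernel bandwidths, and small
g values such as 2⁻⁴ are the empirically selected optima. `zscore` and
`none` remain available as options.

Model selection: exhaustive grid over c, g ∈ {2⁻⁵, …, 2⁵} (11 × 11 =
121 pairs), each scored by full jackknife accuracy; among maximizers
the smallest c, then the smallest g, wins — a deterministic rule, so
repeated searches (and searches over permuted datasets) return the
same pair.

## Evaluation

Jackknife = leave-one-out: n fits on n − 1 samples. Every class must
have at least two members (otherwise some fold would train without the
held-out class entirely); singleton-class datasets are rejected before
any fitting. From the n held-out predictions a confusion matrix (rows
true, columns predicted) yields one-vs-rest TP/TN/FP/FN per class and

    Sn = TP/(TP+FN),  Sp = TN/(TN+FP),
    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FN)(TN+FP)),
    Acc = Σᵢ TPᵢ / N.

The MCC denominator carries the square root of the standard Matthews
coefficient; the formula is sometimes printed without it, but only the
square-rooted form is a correlation bounded by [−1, 1] (equivalence
with the Pearson correlation of the indicator vectors is tested to
1e−12). Any zero denominator factor yields 0 rather than an exception.

## Synthetic data

The generator emulates the shape of the curated localization
benchmarks: a few classes, tens of proteins each, lengths in the
hundreds. Residues are drawn i.i.d. from per-class probability
vectors; the optional motif overwrites a fixed k-mer every `period`
residues, creating the regular spacing that the interval features
detect (motif classes show measurably lower D(k) for the motif's
reduced letter). One integer seed determines everything; per-class
streams are spawned from it, so datasets are reproducible and adding a
class never perturbs existing ones.

The standard two-class benchmark (30 sequences per class, lengths
100–200, 70% residue mass on the strongly hydrophilic vs the strongly
hydrophobic group) is a deliberately strong compositional contrast —
comparable to cytosolic vs membrane proteins — sized so the whole
grid search finishes in well under a minute on one CPU. What passing
on it shows: the full pipeline (encode → features → fuse → classify →
jackknife) recovers a planted class structure, with the distance model
above 0.9 accuracy and the SVM at least matching it. What it does not
show: performance on real proteomes, where class differences are far
subtler, classes overlap, and homology structures the data; i.i.d.
residue sampling has no grammar, domains or evolutionary correlation.

## Numerical choices and degenerate inputs

* Empty sequences and non-standard residues are rejected at the
  boundary (parse/validate), so feature code never sees them.
* Variance is clipped at 0 against the tiny negative round-off of the
  moment form E(x²) − E(x)²; agreement with the direct pmf variance is
  tested to 1e−9.
* Nearest-centroid and grid-search ties break by fixed order (class
  order; smallest c then g) — no randomness anywhere in inference.
* `filter_min_length` keeps sequences of exactly the threshold length
  ("shorter than" semantics) and is idempotent.

## Known limitations

* Feature values tied to the hexagon convention are not comparable
  across tools that place the hexagon differently; only
  geometry-invariant comparisons are meaningful.
* The I(k) sentinel conflates absent and perfectly periodic letters.
* PseAAC parameters of published benchmark results are generally
  unreported; with unknown (λ, w) exact published accuracies are not
  reproducible even on identical data.
* No homology reduction is implemented beyond exact-duplicate
  detection; jackknife estimates on redundant datasets are optimistic.
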