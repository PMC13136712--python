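# Methods

This note documents the models, conventions and numerical choices behind
`featkit`, in the spirit of a statistical-software methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Sequence conventions

Sequences are uppercase strings over `{A, C, G, T}` plus the alignment gap
`-` and the ambiguity code `N`. Positions are 1-based with position 1
PAM-distal; the default aligned length is 23 (a 20-nt protospacer followed
by a 3-nt NGG-style PAM at positions 21–23), so "PAM-proximal" or "seed"
positions are those near 20. All encoders derive their dimensionality from
the aligned length rather than hard-coding 23, which keeps 3–5-nt toy
examples usable in tests while recovering the conventional feature counts
(NPM 368, BULGES 575, LEP 23, MM 23, 8XL 184, OH 92, OH5C 115, KMER 64/63)
at L = 23.

Choices worth making explicit, since the conventions differ across
published pipelines:

* **LEP ordering** is lexicographic over (guide base, target base):
  AA = 0, AC = 1, …, TT = 15. The encoding is bijective; `decode_lep`
  restores both sequences, which makes the convention auditable.
* **NPM/BULGES cell naming** is `pos{p}_{guide}{target}` — guide base
  first, matching the reading "G→A at position 11" for `pos11_GA`.
* **BULGES** is the full 5×5 grid per position over `{A,C,G,T,-}`, chosen
  so NPM is an exact sub-encoding (the 4×4 block) and both bulge
  orientations are representable. The gap-gap cell is structurally
  impossible (record invariant) and stays identically zero.
* **OH pairing** is a bitwise OR of the two one-hots: matched positions
  carry one set bit, mismatched positions two. This loses which strand
  carried which base but keeps dimensionality at 4L.
* **OH5C** is a five-channel one-hot whose fifth channel `X` fires for `-`
  or `N`; it is the only encoder that accepts `N`. Other encoders reject
  `N` with an explicit error rather than dropping records silently.
* **KMER** uses the full 4^k vocabulary by default. The
  `kmer_compact` option drops the lexicographically last k-mer (TTT at
  k = 3), the standard remedy for the compositional collinearity of a
  closed count vector, yielding the commonly printed 63-feature variant.
  For the KO task k-mers are counted on the off-target sequence (the
  compositional context of the cleavage site); for BE, on the gRNA.
* **Distance** is the Hamming-style count of differing aligned columns; a
  gap facing a base counts as one edit. It always equals the sum of the MM
  vector, a cross-check asserted in the tests.
* **Melting temperature** uses the Wallace rule 2(A+T) + 4(G+C),
  appropriate for short oligos; **folding energy** shells out to RNAfold
  and degrades to an omitted column when no folding tool is on PATH.

## Preprocessing

KO read counts are transformed as y′ = log(y + 1) (natural log; the base is
configurable) before regression; predictions are reported back on the count
scale via exp(y′) − 1. Labels are strict: a KO site is active iff its count
exceeds 100 (a count of exactly 100 is inactive); a BE guide is active iff
z < −2.0 (exactly −2.0 is inactive).

Class weights equalize total class mass: active samples receive
`n_inactive / n_total`, inactive samples `n_active / n_total`. Only the
active-class weight is conventionally quoted; assigning the complementary
weight to the inactive class (rather than 1) preserves proportional
contribution while keeping total weight equal to n. Weights are recomputed
on each training fold, never on pooled data, and are applied to both
classification and regression fits (activity labels are available in both
framings, and down-weighting the inactive mass matters most for the
heavily imbalanced KO regression).

## Cross-validation

All records of a guide share its sequence, so sample-level splits leak
context. Grouped schemes permute the distinct guide ids with the seed and
chunk them contiguously: `leave_one_group_out` holds out one guide per
fold; `leave_k_groups_out` forms k mutually exclusive guide sets (with 110
guides and k = 10, eleven guides per fold). The BE screen has one record
per guide and uses ordinary shuffled k-fold. A leakage assertion (no guide
in both train and test of a fold) runs on every experiment.

## Models

Classification uses logistic-loss XGBoost, regression squared error on the
transformed target. Defaults: 300 trees, depth 6, learning rate 0.1,
λ = 1, α = 0, no subsampling, single-threaded `hist` growth — deterministic
given the seed. The randomized hyperparameter search samples learning rate
and regularization terms log-uniformly (η ∈ [0.01, 0.3]; λ, α ∈ [10⁻³,
10]), depth in {3..10}, trees in {100..1000} and row/column subsampling in
[0.6, 1], scoring each candidate by mean cross-validated AUPR
(classification) or Pearson r (regression) on the supplied fold plan.

## Metrics

AUPR uses the average-precision estimator Σ (R_i − R_{i−1}) P_i over
distinct score thresholds, with tied scores grouped into one step and no
linear interpolation — conservative under heavy imbalance, invariant to
monotone score transforms, and equal to the exhaustive-threshold brute
force (asserted against it, and against scikit-learn, in the tests). AUROC
is the Mann–Whitney rank statistic with half credit for ties. Thresholded
metrics (F1, accuracy, precision, recall) default to a 0.5 cut; when no
sample is predicted positive, precision and F1 are reported as 0 with an
explicit flag.

KO regression correlations (Pearson, Spearman) are computed on
active-labeled sites only, on the count scale; RMSE is computed over all
sites on the count scale after back-transform, which is why its magnitude
is dominated by the active tail. BE metrics use all records on the z
scale. Correlations need at least three usable points and are otherwise
reported as undefined rather than silently dropped.

The tail-error analysis flags the ⌈10%⌉ largest absolute errors and
stratifies the signed error (predicted − true) by true z
(< −4, [−4, −2), [−2, 2], > 2). A mean-reverting predictor shows positive
mean signed error in the left strata — under-prediction of effect
magnitude, the characteristic failure of boosted regression in
data-scarce tails.

## Explainability

Attributions are exact TreeSHAP values computed by the tree ensemble on
its additive raw-margin scale (log-odds for classification), the scale on
which the local-accuracy identity Σφ + base = f(x) is exact. The ensemble
evaluates in single precision, and summing a 300-tree model in float32
leaves round-off of a few 10⁻⁶; contributions are therefore accumulated
over small tree chunks in double precision (per-tree if needed) with a
zero base margin, the intercept added back once. The identity is verified
at 10⁻⁶ relative for every sample before a report is returned. Global
importance is mean |φ| — the ordering of conventional SHAP summary plots —
with the usual caveat that aggregating local attributions is a summary,
not a causal decomposition. Positional roll-ups sum mean |φ| over features
sharing a `pos{p}` prefix and conserve total positional mass.

First-order ALE estimates a feature's marginal effect from local finite
differences within feature bins, remaining meaningful when features are
correlated — the relevant case, since `distance` is a deterministic
function of the sequence features. Integer-valued features such as
distance get one bin per observed value; continuous features get quantile
bins (default 20). Effects are accumulated across bins and centered so the
sample-weighted mean effect is zero. ALE curves are computed on the
raw-margin scale. On classification margins the synthetic KO signal
saturates above ~3 mismatches (such sites are almost surely inactive, so
the trees stop splitting there and the curve ties at its floor);
monotonicity checks of the distance effect therefore use the regression
model, whose log-count target keeps falling through six mismatches.

## Synthetic data

The simulators define the study conditions for all pipeline tests; they
emulate the statistical structure of the real screens, not their genomic
sequence composition.

**KO simulator** (defaults: 20 guides × 500 sites, seed region 13–20,
β₀ = 6.0, β_mm = 1.2, seed multiplier 2.0, NB size 2.0, target active
prevalence 3%). Each guide is a random 23-mer with a fixed GG at positions
22–23. Each site draws a mismatch count m from a two-component mixture:
a low-distance component concentrated at m ∈ {0, 1} (weights 0.6/0.4) and
a high-distance component with weights ∝ exp(0.8 m) for m ≥ 2, reflecting
that candidate-site abundance grows steeply with the allowed mismatch
count in genome-wide enumeration. The mixing fraction is solved in closed
form so the expected fraction of sites with count > 100 equals the target
prevalence, using the exact hypergeometric distribution of seed-region
hits and the negative-binomial survival function — the imbalance is thus
controlled mechanistically through the distance distribution, keeping
distance and label linked as in real data rather than by post-hoc
subsampling. Mismatch positions are uniform over the protospacer (the PAM
is left intact, as candidate sites share it); substituted bases are
uniform over the three alternatives. The log mean count is
μ = β₀ − β_mm·(burden), where seed-region mismatches contribute double
burden, and the read count is negative-binomial with mean exp(μ) —
overdispersed, as sequencing counts are.

**BE simulator** (defaults: 5,000 guides, noise SD 0.6, target z < −2 tail
8%). z is a sum of per-position nucleotide effects concentrated at
PAM-proximal positions (strongest: A at position 20, −1.0; A at 17, −0.8),
small trimer motif effects (GGC −0.25, AAA +0.2), and Gaussian noise,
then affinely calibrated (standardized, shifted) so the empirical
tail-fraction quantile sits at −2. A near-constant raw z raises an
explicit degenerate-variance error instead of producing an arbitrary
calibration.

All randomness flows from one integer seed through a counter-based stream
per guide, so a guide's records are invariant to how many other guides are
simulated. `inject_bulges` inserts a single gap column (guide- or
target-side, equiprobable) into a chosen fraction of pairs for testing the
BULGES encoder.

What the simulators do **not** reproduce: human-genome sequence
composition and its k-mer biases, PAM-variant effects, chromatin or
epigenetic context, inter-guide count correlation, and real bulge
alignment ambiguity. Tests passing on synthetic data therefore validate
the machinery (encodings, weighting, grouped CV, attribution mechanics)
and the qualitative signal structure, not real-data performance levels.

## Problem sizes in the test suite

The pipeline tests run the KO simulator at its default 20 × 500 scale over
three seeds with five guide-group folds, and the BE simulator at 5,000
guides with 10-fold CV — sizes at which the boosted-tree behaviour of
interest (distance dominance, One-Hot vs K-mer separation) is stable and
the full suite completes in a couple of minutes on one core.

## Known limitations

* OH pairing discards which strand carried which base; NPM/BULGES keep it.
* The fifth-channel semantics of OH5C (gap/N) are a parsimonious
  convention; other conventions exist in the literature.
* The KO regression RMSE is reported on the raw count scale and is
  dominated by the heavy active tail; compare models by correlation as
  well.
* TreeSHAP exactness applies to the tree ensemble itself; attributions on
  the probability scale (not provided) would require a different,
  approximate propagation.
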