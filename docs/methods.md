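# Methods

## Model

The activity model is ordinary least squares in raw descriptor units,

    y = a0 + a1 x1 + ... + ak xk + e,

with y the pIC50 (−log10 of the molar IC50) and x1..xk molecular
descriptors. No scaling, weighting or regularization is applied: the
coefficients are meant to be read in descriptor units, as QSAR equations
conventionally are. The solver is an orthogonal decomposition (LAPACK
`gelsd` through `scipy.linalg.lstsq`); a design matrix whose smallest
singular value falls below 1e-10 of the largest is rejected as
rank-deficient, with the dependent columns identified by pivoted QR. A
unit test checks the solution against an exact rational-arithmetic
normal-equations oracle and against an independent OLS implementation.

Fitting statistics: R² = 1 − RSS/TSS with TSS about the training mean,
R²_adj = 1 − (1−R²)(n−1)/(n−k−1), and RMSE = √(RSS/n). The divisor n in
the RMSE (rather than n−k−1) is deliberate: it is the convention under
which the built-in study's printed RMSE of 0.082 reproduces from its own
training data.

## Internal validation

Q²_LOO = 1 − PRESS/TSS, where PRESS uses the exact leave-one-out
identity: the deleted residual of compound i is e_i/(1 − h_ii) with h_ii
the hat-matrix diagonal, so no refitting is needed. TSS uses the
full-training-set mean (the standard PRESS convention, not fold-wise
means). The shortcut is asserted equal to n literal refits to 10
significant digits, both in a property test on random data and on the
built-in study.

On the built-in training set Q²_LOO computes to 0.6331. The published
report prints 0.633 in one place and 0.649 in another (the two values are
swapped with the external statistic between the two places); the
validation report states which printed value the computation matches
rather than hard-coding either pairing.

## External validation

Because the single published "R²_ext" is not accompanied by a formula,
all four standard candidates are always reported:

- Q²_F1 = 1 − Σ_test (y−ŷ)² / Σ_test (y−ȳ_train)²
- Q²_F2 = same with the test-set mean in the denominator
- Q²_F3 = 1 − (PRESS_ext/n_ext)/(TSS_train/n_train)
- squared Pearson correlation of observed vs predicted on the test set

On the built-in 6-compound test set these are 0.598, 0.366, 0.658 and
0.645; the Pearson r² and Q²_F3 are the values closest to the published
0.633/0.649.

## Y-randomization

Each iteration permutes the activity vector uniformly at random (seeded
`numpy` Generator stream), refits the same descriptor subset, and records
R (= √R², the correlation of fitted and observed values in an
intercept-containing OLS fit), R² and Q²_LOO. The default is 500
iterations — the published iteration count is unstated; 500 gives a
Monte-Carlo standard error on the mean R² of about 0.002 for the built-in
study, far below the reporting precision. For a k-descriptor fit to an
exchangeable response the expected R² is k/(n−1) ≈ 0.19 at k=5, n=27,
which is what the permutations produce and what the published 0.195/0.196
reflects.

cRp² = R·√(R² − R̄_r²) uses the *mean correlation* of the randomized
models, not the mean squared correlation: with the built-in study's
printed mean correlation 0.428 this evaluates to 0.669, matching the
published value, whereas the mean-R̄² variant gives ≈ 0.662 and was
rejected on that ground. A negative radicand is truncated to 0 with a
warning flag.

## Applicability domain

Leverage h = x'(X'X)⁻¹x against the training design matrix, warning
leverage h* = 3(k+1)/n, standardized residuals, and Williams
classification: in-domain ⇔ h ≤ h* and (where a residual is defined)
|r| ≤ 3. The boundary h = h* counts as inside (the threshold criterion is
strict inequality on the outside; exact equality is measure-zero).
Query compounds have no observed activity and are classified on leverage
alone.

Two leverage conventions are exposed because both exist in practice:

- `include_intercept=True` (default): rows are augmented with an
  intercept entry, giving the textbook hat matrix. Training leverages lie
  in [1/n, 1] and sum to k+1, consistent with the k+1 parameters behind
  h*.
- `include_intercept=False`: the formula applied verbatim to the raw
  descriptor rows. This is the convention under which the built-in
  study's published leverages reproduce exactly (e.g. designed compound
  P14: 0.358 raw vs 0.484 intercept-augmented); the reproduction scripts
  therefore use it when comparing to the published table.

Under either convention all 33 synthesized and 7 designed compounds of
the built-in study fall inside the domain.

Standardized residuals divide by s = √(RSS/(n−k−1)), the conventional
residual standard error, with the RMSE-divisor variant exposed as an
option; test-set residuals are standardized by the same training s.

## Pruning

The near-constant filter drops a descriptor iff its modal value occupies
strictly more than 95% of rows; values are compared after rounding to 12
significant digits so float noise cannot hide a constant. The
collinearity filter removes exactly one member of every pair with
Pearson |r| > 0.90, sweeping pairs by descending |r| (deterministic
tie-breaks); within a pair the member less correlated with the activity
is dropped, the later column on an exact tie — keeping the more
activity-relevant descriptor while staying reproducible. Pruning is
idempotent and preserves column order. Zero-variance columns are a hard
error directing the caller to run the constant filter first.

## GA subset selection

Chromosomes are sorted descriptor-index sets with sizes in
[size_min, size_max] (default 4–6); fitness is Q²_LOO on the training
rows, cached per subset. Selection is binary tournament, crossover
samples a child from the union of two parents (size repaired to bounds),
mutation swaps one member for a random non-member, duplicates are
repaired by resampling, and two elites are carried over unchanged — so
the best fitness is non-decreasing by construction. Defaults (population
100, 200 generations, crossover 0.9, mutation 0.1) are declared choices:
no published GA hyperparameters exist for the original search, whose
software internals are proprietary. Everything is driven by one seed, and
the same seed, data and configuration give a bit-identical result. An
exhaustive enumerator (budget 10⁶ subsets) provides the exact global
ranking on small pools and serves as the GA's correctness oracle in the
tests.

## Synthetic data

The generator emulates a curated QSAR table: i.i.d. standard-normal
descriptors, a linear response from a planted subset with stated
coefficients plus Gaussian noise, a seeded plain-random 80/20 split, and
two engineered pathologies — collinear pairs (partner = primary + jitter
scaled so the population correlation is 0.97, comfortably above the 0.90
pruning threshold for n ≥ 50) and near-constant columns (one value on a
0.97 share of compounds, above the 0.95 criterion by construction).
Gaussian marginals and independence are deliberate simplifications: real
descriptor blocks have heavy-tailed, discrete and mutually correlated
columns. Passing tests on synthetic data therefore demonstrate the
correctness of the algorithms under the stated generative model, not
performance on real descriptor distributions.

Benchmark problem sizes used in the tests and analysis scripts — planted
5-of-40 subsets at n = 150–200 compounds and noise SD 0.05, GA oracle
pools of C(10,4) = 210 subsets, 100-seed coefficient-recovery runs — were
chosen as the smallest instances at which the statistical claims (≥ 95%
subset recovery, ±3 SE coefficient recovery in ≥ 99% of checks) are
meaningful.

## Degenerate inputs and numerical choices

- Constant response (zero TSS): hard error, R² undefined.
- n ≤ k+1: hard error for fitting; n ≤ k+2 for LOO.
- A leave-one-out fold with leverage 1 (fold rank-deficient): hard error.
- Fewer than two test compounds: Pearson r² and Q²_F2 are reported as
  undefined (NaN) rather than fabricated.
- JSON reports write floats at full precision, so written results
  round-trip exactly.

## Known limitations

- The descriptor-computation step (PaDEL or similar) is out of scope:
  descriptor values are consumed as given, and the package cannot verify
  them against structures.
- The pruning count of the original >800-descriptor pool is not
  reproducible from the shipped data, which contain only the five curated
  descriptors.
- No bootstrap validation, Golbraikh–Tropsha criteria, or concordance
  correlation; no VIF- or clustering-based redundancy removal; no
  multi-objective GA.
- Williams-plot *rendering* is left to the caller; the package emits the
  plot-ready table (compound, leverage, h*, standardized residual,
  flags).
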