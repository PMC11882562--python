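# Methods

`teacat` implements the inference chain that links season-aggregate
meteorological conditions to catechin accumulation in tea (*Camellia
sinensis* cv. Tieguanyin) leaves, for the 10-site x 3-season plantation
study design. This note records the models, the defaults and their
rationale, the numerical choices, and what the synthetic-data tests do and
do not establish.

## Study design and data model

The unit of analysis is a (site, season) record carrying eight
season-aggregate meteorological factors (canonical order x1..x8: rainy-day
mean rainfall mm/day; average, maximum and minimum air temperature degC;
effective accumulated temperature EAT degC; relative humidity %RH; 10-cm
ground temperature degC; daily irradiance lux) and the seven catechin
monomer concentrations in percent dry leaf mass (EGC, C, EC non-esterified;
EGCG, GCG, ECG, CG esterified). Biological replicates are averaged upstream
(`average_replicates`); the pipeline consumes per-record means. Group sums
TEC (esterified), TNEC (non-esterified) and TC are derived quantities,
never stored, so they are exact by construction.

### Feature construction

* **EAT.** The per-day excess of mean temperature over the biological zero
  (10 degC for tea), averaged over the observation period. The
  growing-degree convention of clipping negative daily excess at zero is
  the default, with `clip_negative=False` exposing the literal signed
  average; for the seasonal data the two coincide whenever all days sit
  above the zero. Note the published optimal conditions carry EAT values
  in the hundreds, on a seasonal-accumulation rather than per-day scale;
  the pipeline therefore treats the `eat` column as an opaque bounded
  covariate and never re-derives it from daily series.
* **Rainy-day rainfall.** Total rainfall on days with measurable
  precipitation divided by the number of such days. "Measurable" defaults
  to strictly above 0 mm and is configurable (e.g. >= 0.1 mm); a period
  with no rainy days yields 0 with a logged warning instead of a
  division by zero.

## PLS1 and VIP screening

Each response (catechin or log-relative gene expression) is regressed on
the eight factors by single-response partial least squares, extracted
sequentially by NIPALS after autoscaling both X and y (mean 0, variance 1
-- the chemometrics default when predictors mix millimetres with lux; VIP
is computed in this scaled space). Extraction is deterministic and stops
early when the residual covariance vanishes. The component count is chosen
by leave-one-out RMSECV, capped at min(n-1, 8), ties broken toward fewer
components.

Variable importance uses Wold's VIP,

    VIP_j = sqrt( p * sum_a SS_a (w_aj)^2 / sum_a SS_a ),

with unit-norm component weights w_a and SS_a = q_a^2 t_a't_a the response
variance explained by component a. The normalization sum_j VIP_j^2 = p
holds identically, so VIP > 1 (strict) flags factors carrying more than an
equal share of importance; that threshold defines the factor-response link
lists the screening stage emits.

## Per-catechin regression and error metrics

Each monomer is fitted by ordinary least squares on all eight factors
(y = b0 + b . x, percent dry mass). Model quality is reported as RMSEC
(root mean squared calibration residual), RMSECV (out-of-fold error,
leave-one-out by default; k-fold assignment requires an explicit seed) and
RMSEP (error of the calibrated model on a held-out test set; the default
split is season-stratified 70/30 with a mandatory seed). Rank-deficient
designs are rejected with the collinear columns named. Predictions may be
negative -- a property of the linear equations near the box boundary --
and are flagged by a logged warning, never silently clipped.

A published seven-equation coefficient table for Tieguanyin tea ships as a
data fixture (`load_table1`), used for worked examples and as the ground
truth of the synthetic generator. A VIP-restricted regression variant and
a PLS-regression-vector export exist behind flags for comparison; the
all-eight-factor OLS is the default and the basis of everything downstream.

## Constrained optimization of growing conditions

For a target catechin the optimizer maximizes its predicted concentration
over the box of observed factor ranges, with the other members of its
chemical group (TEC or TNEC) held between thresholds -- by default each
co-member's observed concentration range:

    max  b0_t + b_t . x
    s.t. low_j <= x_j <= high_j,   lo_m <= b0_m + b_m . x <= hi_m.

Box-only problems are solved in closed form by the sign rule (each factor
to its upper bound iff its coefficient is strictly positive, else lower --
the tie at 0 resolves to the lower bound, which is also the
lexicographically smallest optimum). Grouped problems go through the HiGHS
simplex solver, followed by a sequential lexicographic refinement
(coordinate-by-coordinate minimization subject to near-optimality within
1e-9 relative) so ties are broken deterministically; any refinement-stage
solver failure falls back to the incumbent vertex. Feasibility of reported
solutions is 1e-9; infeasible problems return a certificate naming a
single unreachable threshold when one exists. An exhaustive 256-vertex
oracle validates the solver on box-only problems.

The demo factor box spans the published optimal-condition vectors (its
temp_min interval is degenerate at -3.6 degC because all published optima
share that value). The published C optimum is exactly the sign-consistent
vertex of the C equation and is reproduced coordinate-for-coordinate; the
published EGCG optimum is *not* a sign-consistent vertex of the EGCG
equation (its EAT and irradiance coordinates sit at the opposite bounds),
implying the original optimization carried additional weighting or binding
constraints that the publication does not specify. The package therefore
treats the published optima as evaluation points for the worked examples
and validates its own optimizer by oracle equivalence rather than by
matching that argmax. An optional VIP-weighted objective is available
behind a flag for exploring that hypothesis.

## qPCR expression processing

Relative expression is 2^-ddCt against a reference gene (GAPDH) and a
reference sample, replicate Cts averaged on the cycle scale first; the
reference sample's column is exactly 1 for every gene. Per-season versus
global reference normalization is a flag (per-season default).
Amplification efficiency comes from a cDNA dilution series (5x/25x/125x
design): E = 10^(-1/slope) - 1 with the slope of Ct on log10 relative
concentration; perfect doubling gives E = 1 exactly, and slopes outside
(-10, -1) cycles/decade trigger an implausibility warning. Heatmap-style
reports use the log2 matrix with a deterministic Euclidean
hierarchical-clustering leaf order (average linkage by default,
complete/single/ward configurable; labels are pre-sorted so distance ties
resolve identically across runs). Rendering is left to plotting layers.

## Descriptive statistics

Pearson correlation reports carry two-sided t-test p-values and the star
convention * (0.01 < p <= 0.05), ** (0.001 < p <= 0.01), *** (p <= 0.001);
no multiple-testing correction by default, Benjamini-Hochberg behind a
flag. PCA of the seven catechin profiles runs on the correlation matrix
(standardized variables) by default, so squared component standard
deviations sum to 7; covariance PCA is a flag. Loading signs are fixed by
making each vector's largest-magnitude entry positive.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
tested: 10 sites x 3 seasons, factors drawn independently and uniformly
inside the demo box, catechins from the published equations plus Gaussian
noise, optional Ct tables whose implied 2^-ddCt follows a configured
log-linear factor response.

Defaults and their rationale:

* **temp_min upper bound 12.72 degC.** The published optima pin temp_min
  at -3.6 degC, giving no upper bound; 12.72 (the low end of the temp_avg
  range) keeps the temp_min <= temp_avg <= temp_max ordering intact
  without repair at default bounds. Out-of-order draws under custom
  bounds are repaired by sorting the temperature triple, with the count
  logged.
* **Noise = published RMSEC x 10 per response.** The published
  calibration errors (e.g. 0.0156% for EGCG against ~12% concentrations)
  are implausibly small as generative noise; scaling by 10 yields a
  stated convention, not an estimate of the study's true noise, which is
  unknowable from the publication.
* **Negative concentration draws are floored at 0** (not resampled), with
  the count recorded so tests can assert rarity at default noise.
* An optional correlation knob can induce the temperature/EAT
  collinearity real data would show, for stress-testing VIP screening.

What passing tests show: the chain recovers generating coefficients
exactly in the noise-free limit, its error metrics order correctly under
noise, the VIP screen finds a planted single driver reliably at n = 300,
and the optimizer equals brute-force enumeration. What they do not show:
performance under the real data's factor collinearity, non-linear
responses, measurement error in the meteorology, or site-level random
effects -- none of which the independent-uniform generator emulates. The
published data-dependent statistics (variance shares, loadings, error
magnitudes) are not reproducible without the undeposited study data and
are deliberately not asserted.

## Problem sizes and determinism

The test suite and the acceptance script run the generator at n = 30
(the study layout) and n = 100-300 sites for consistency checks, 100-200
replicates for the simulation studies, and full 256-vertex enumeration
for the optimizer oracle. Every stochastic step -- generation, fold
assignment, train/test split -- takes an explicit integer seed and is
bit-reproducible; pipeline runs with the same seed produce byte-identical
artifacts.
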