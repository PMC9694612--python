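# Methods

## The modelling problem

A factorial aniseed (*Pimpinella anisum* L.) field trial crosses two growing
years, three localities and six fertilization treatments (an unfertilized
control, two microbiological preparations, two organic biohumus products and
mineral NPK), with four replicate plots per cell (2 × 3 × 6 × 4 = 144
records).  Thirty responses are recorded per plot: thirteen agronomic traits
(plant height through essential-oil content) and seventeen essential-oil
composition shares, one of them an unidentified chromatographic fraction
("NI").  The package models all thirty responses jointly as a function of
the three categorical factors, quantifies each factor level's influence, and
searches for growing conditions that maximize all responses simultaneously.

## Network model

The regression model is a single-hidden-layer perceptron in matrix form

    Y = f1(W2 · f2(W1 · X + B1) + B2)

with `X` the N × 10 encoded input matrix (one 0/1 year code, three locality
indicators, six fertilization indicators), `W1`/`B1` the input-to-hidden
weights and biases, `W2`/`B2` the hidden-to-output ones, `f2` the hidden and
`f1` the output transfer function.  Both transfer functions come from
{identity, logistic, tanh, exponential}; the reference architecture is
MLP 10-10-30 with exponential activations in both layers.  A 10-10-30
network has 10·10 + 10 + 10·30 + 30 = 440 weights and biases; the package
reports this true count.  (The source study quotes "208 weights-biases" for
the same architecture; that figure is inconsistent with 10-10-30 and the
discrepancy is left unresolved — we report the count implied by the shapes.)

The loss is the plain sum of squares (SOS) over all rows and outputs of the
[0, 1]-scaled responses.  The gradient is computed analytically by
backpropagation (validated against central finite differences) and passed to
a BFGS quasi-Newton optimizer with strong-Wolfe line search (SciPy's
implementation), capped at 1000 iterations by default.  Because the SOS
surface is multimodal, training restarts from `restarts` independent random
initializations — weights and biases uniform in [−0.5, 0.5] — and the
restart with the smallest **validation** SOS is kept.  The default restart
count is 50; the original protocol's very large replication count covered an
entire architecture grid and is impractical verbatim, so the default is
desk-scale with a configuration path to any larger count.  An architecture
search scans hidden sizes 5–20 × the requested activation pairs and keeps
the grid point with minimal validation error.

Data handling: rows are split 60/20/20 into training/validation/test by
uniform random partition (sizes rounded half-up, remainder to training; 36
rows give 22/7/7), unstratified by factor cell.  Responses are min–max
scaled to [0, 1] using extremes of the **training partition only**; inputs
are left as raw 0/1 codes since they are already bounded.  Values outside
the training range are deliberately not clipped so the scaling stays
invertible for error reporting in original units.  Degenerate (constant)
response columns map to the interval midpoint and are flagged.

The per-partition "performance" statistic is the mean over the 30 outputs of
the squared Pearson correlation between observed and predicted values.  The
aggregation rule (mean) is our declared choice; per-output r² values are
also available from the fit tables.  SOS errors are reported both in
normalized and in original units, since either convention is defensible.

## Goodness of fit

Per response, for observations x_exp and predictions x_pre (length N, n
model constants):

* reduced chi-square χ² = Σ(x_exp − x_pre)² / (N − n)
* RMSE = √(Σ(x_pre − x_exp)² / N)
* mean bias error MBE = mean(x_pre − x_exp)
* mean percentage error MPE = 100/N · Σ |x_pre − x_exp| / x_exp
  (absolute relative error, despite the "percentage error" name)
* r² = squared Pearson correlation of (x_exp, x_pre)
* bias-adjusted sample skewness and **excess** kurtosis of the residuals
  (a normal sample gives 0), plus residual mean, SD and variance (ddof 1).

Identities used as invariants: χ² = RMSE²·N/(N−n); MBE equals the residual
mean; RMSE² = MBE² + s²·(N−1)/N.  Edge rules: any zero observation makes
MPE undefined (reported missing with a warning, not an exception); n ≥ N
makes χ² missing; zero variance in either vector makes r² missing.  The
constant count n defaults to 1 per response and is configurable — published
fit tables of this kind rarely state N or n, so both are explicit inputs
here.

## Connection-weight (Yoon) sensitivity

Input influence is read off the trained weight matrices:

    RI_ij(%) = Σ_k (w_ik · w_kj) / Σ_i |Σ_k (w_ik · w_kj)| · 100

with k over hidden units.  The denominator sums over inputs, so each output
column's absolute importances total 100% and signs give the direction of
influence.  Biases are excluded.  The measure is invariant to a global
positive rescaling of either matrix but not to per-input rescaling of `W1`;
importances are therefore computed on the weight scale the network was
trained on (inputs being 0/1 codes, no input scaling is applied anyway).

One structural caveat documented here because it shapes both the synthetic
defaults and the validation: each one-hot indicator block sums to one, so
adding a constant to a factor's block of `W1` rows (compensated in `B1`) does
not change the fitted function.  Connection-weight signs for one-hot inputs
are therefore only meaningful relative to the factor's internal contrasts.
The synthetic generator keeps each factor's effects centred near zero per
response so the generating signs are identifiable, and the sign-recovery
validation trains with a linear output layer (tanh/identity), where the
near-linear small-weight regime makes the connection-weight products track
the generating effects closely.  With exponential/exponential activations
the fit quality is equal but sign agreement is noticeably weaker — a genuine
limitation of connection-weight sensitivity on saturating/convex
activations, not an implementation artifact.

## Multi-objective optimization

All 30 predicted responses are maximized simultaneously over the growing
conditions.  Two decision spaces are supported:

* **discrete** (default): genomes are factor-level triples.  The space has
  only 36 points, so the exact Pareto front is computable by enumeration +
  nondominated filtering; this exhaustive oracle is what the genetic
  algorithm is verified against.
* **relaxed**: genomes are the raw 10-dimensional input vectors with each
  coordinate free in [0, 1], mirroring a continuous treatment of the encoded
  factors.  (A continuous treatment is how a reference run of this kind can
  report a front of hundreds of points; reproducing any specific front size
  is not a goal.)

The GA is an NSGA-II loop: fast nondominated sorting, crowding distance,
binary tournament selection, uniform crossover (per-gene swap in discrete
mode, per-coordinate blend in relaxed mode) with probability 0.9, and
per-gene mutation with probability 1/genome-length (random level reset /
clipped Gaussian step σ = 0.1).  Population 100, up to 200 generations with
early stop after 20 generations without archive change.  The returned front
is the nondominated subset of an archive of **all** individuals ever
evaluated, so front members cannot be lost to generational replacement.
Per-output optima are read off the front, ties going to the earlier member.

## Synthetic trial generator

Each response is generated additively:

    y = intercept + year_effect · year_code + locality_effect
        + fertilization_effect + gain · year_code · fertilization_effect + ε

with ε ~ N(0, noise_sd²) independent per plot, and `gain` an optional
year × fertilization interaction (default 0) that gives the perceptron
genuine nonlinearity to learn when wanted.  Essential-oil shares are clipped
at zero after the noise draw and are *not* renormalized to 100% (each
compound is modelled independently and the roster contains an unidentified
fraction).  Year is coded 0/1 so a single signed year effect suffices.

Default parameter tables: intercepts sit at typical observed levels of each
trait (e.g. plant height ≈ 46 cm, trans-anethole ≈ 90% of the oil — the
dominant phenylpropanoid; seed yield ≈ 1.9 t/ha), noise_sd reflects
plot-to-plot replicate scatter of each trait (e.g. 1.4 cm for plant height,
0.02–0.75 percentage points for oil shares), and the strongest factor
effects span roughly 15–20% of the intercept.  Directions of influence
follow the agronomic pattern the package is built around: vermicompost and
BactoFil raise growth and yield traits; Royal Ofert and mineral NPK depress
seed quality, yield and germination while favouring trans-anethole; NPK and
the second year favour the himachalene/zingiberene sesquiterpene group; site
contrasts drive the minor monoterpenes.  Within each factor the effects are
balanced to sum ≈ 0 per response (see the sensitivity section); levels with
no documented direction receive small seed-dependent jitter.

What the generator does *not* emulate: weather covariates (growing degree
days, precipitation, insolation) beyond the year/locality labels,
block-position effects within the randomized block layout, correlated noise
across responses, and compositional closure of the oil shares.  Passing
tests therefore demonstrate the correctness of the modelling chain under
known additive ground truth, not field realism.

## Numerical choices and degenerate inputs

* BFGS gradient tolerance 1e-10, iteration cap 1000 (reference run
  converged within that); non-finite runs are discarded and logged, and
  training fails only if every restart diverges.
* Exponential activations can overflow for large pre-activations; overflow
  produces an infinite loss for that evaluation, which the line search
  retreats from, and a run ending non-finite is discarded.
* Restart selection uses validation SOS; without a validation set it falls
  back to training SOS.
* Split rounding: half-up per partition, remainder rows to training.
* Pareto filtering keeps all duplicates of a kept point; ranking ties keep
  input order; per-output optima ties keep the earlier front member.
* CSV exports use 17 significant digits so round trips are bit-exact.

## Validation problem sizes

The test and acceptance runs use the full 144-record synthetic trial with
the reference 10-10-30 architecture; restart counts of 6–50 and iteration
caps of 300–500 keep each training run at desk scale while leaving the
protocol itself unchanged.  The teacher-recovery check (zero-noise targets
from a known exponential network, 50 restarts) reaches overall training
r² ≈ 0.99, and the sign-recovery check (five seeds, low noise) agrees with
the generating signs for ≈ 89% of the top-5 effects per response.  The GA is
checked for exact front equality against enumeration on ten random networks.

## Known limitations

* Connection-weight sensitivity signs are unreliable for saturating or
  convex activation pairs (see above) and for factor levels whose effects
  are small relative to the factor's balance.
* The χ²/RMSE relationship fixes only N/(N−n); absolute χ² values depend on
  the caller's choice of n.
* The discrete optimization space is tiny by construction; the GA's value
  here is verifiability, not necessity.  In relaxed mode fractional
  indicator vectors have no direct agronomic interpretation; they are an
  extrapolation device.
* Architecture search re-seeds each grid point deterministically; results
  are reproducible but, as with any multistart nonconvex fit, not unique
  across seeds.
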