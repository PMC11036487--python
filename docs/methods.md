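# Methods

This note documents the models, defaults and numerical choices behind
`dbtlopt`, and what the synthetic benchmark studies do and do not show.

## Design space and encoding

A library is an ordered set of factors (cassette slots), each with an
ordered set of levels (promoter + ORF); experimentally unbuildable levels
are listed as exclusions and removed from the effective space, whose size
is the product of the remaining per-factor level counts.  Enumeration
order is fixed — factors by cluster position, levels in declared order,
rightmost factor fastest — so serialized outputs are byte-stable.  The
order is a convention of this package, not a reproduction of any external
enumeration.

Designs are one-hot encoded with **all** levels retained (no reference
level dropped): each row sums to the number of factors and each factor
block sums to one.  Keeping all levels treats levels symmetrically, which
the ranking and the attribution stages rely on; the price is exact
collinearity in the linear design matrix, absorbed by the minimum-norm
least-squares fit (see below).  Promoter-strength labels on levels
(strong/medium/weak) are metadata for reporting and expansion advice only;
they never enter the encoding, so models see purely categorical genotypes.

## Synthetic landscapes and the simulated screen

`LandscapeModel` maps a design to a noiseless titer: baseline + additive
per-level effects + pairwise (factor,level)–(factor,level) interaction
terms, clipped at 0; designated nonproducer levels force a zero titer.
Interactions are restricted to pairs — the smallest structure that gives
nonlinear models something the linear model cannot represent.

`sample_landscape` draws additive effects uniformly from a range
(default ±0.05 au), centered to zero mean within each factor so that the
baseline equals the additive space-mean titer, and gives a random
fraction (default 5%) of cross-factor level pairs an interaction term
(default ±0.02 au).  The canonical simulated campaign
(`dbtlopt.study`) uses baseline 0.09 au and replicate noise 0.01 au, and
simulates 225 sequenced colonies at 84% assembly success over the
672-design reduced library, thinned to 91 unique correct designs.  These
values were fixed once to match the observed scale of the real screen:
simulated titers span roughly 0–0.25 au and on average ~25–30% of designs
fall below the 0.05 au detection limit.  Replicate noise magnitude is a
free parameter (no measured value exists for it); 0.01 au keeps replicate
scatter visibly smaller than between-design differences.

The simulator samples colony designs **uniformly** with replacement.
Real one-pot assembly is biased by cassette abundance, which is why the
real campaign saw far fewer unique designs per sequenced colony than
uniform sampling produces; the study helper compensates by thinning the
unique designs to the campaign's 91, rather than by modeling the bias.
Incorrectly assembled colonies are kept in the colony table with
background-noise titers and a ground-truth flag, mirroring a
screening-before-sequencing workflow where wrong assemblies are only
discovered at sequencing; they are dropped when replicates are collapsed.

What the simulator does **not** emulate: cassette-abundance bias (above),
plate/batch effects (inputs are assumed pre-normalized), non-Gaussian
measurement error, and higher-order epistasis.  Passing benchmarks on
these landscapes therefore shows the pipeline's machinery is sound, not
that real screens satisfy its assumptions.

## Datasets, strata, splits

Replicate colonies are averaged into one row per unique design; the
producer flag uses an inclusive threshold (mean titer ≥ detection limit;
"nonproducer" means strictly below), applied to design-level means
because datasets are defined over unique designs.  The complete dataset
keeps everything; the producers dataset keeps rows at or above the limit.

Production classes are quantile bins (default 4).  On the complete
dataset the nonproducers form class 0 and producers are split into the
remaining 3 quantile bins; the producers dataset is split into 4 bins.
Quantile binning is deterministic and parameter-free; it stands in for
the unspecified clustering that defined the original
poor/medium/good/very-good classes.

Stratified splitting and subsampling allocate per class with
round-half-up, then trim/extend from the largest classes to hit the
global count; singleton classes go wholly to train.  The training-size
sweep compares two complete protocols per repeat: the **stratified arm**
(stratified split + proportion-preserving subsample) against the
**unstratified arm** (uniform split + uniform subsample).  Dropping
stratification only from the subsampling step while keeping a stratified
test split turned out to have no measurable effect on mean R² in this
generator's campaigns; the protocol-level contrast is also what the
screening workflow actually decides (whether to carry production classes
through the campaign at all), and it is the arm definition used
throughout.

## Model families and tuning

Four scikit-learn regressors on the one-hot genotypes: multiple linear
regression (minimum-norm least squares, so the retained-level
collinearity is well defined), RBF-kernel support vector regression,
RBF-kernel ridge regression, and random forest regression (seeded).

All families except the linear model tune hyperparameters by
leave-one-out cross-validation on the training rows, scored by the
**maximum absolute held-out error** (ties broken by grid declaration
order).  Max-error is a deliberately conservative score for datasets of
~30–90 rows, where one badly predicted strain matters more than average
loss.  Default grids (config-overridable conventions):

| family | grid |
|---|---|
| kernel ridge | α ∈ {1e-3…10} (5, log), γ ∈ {0.01…10} (4, log) |
| SVR | C ∈ {0.1…100} (4, log), ε ∈ {0.01, 0.05, 0.1}, γ as KRR |
| random forest | 100 trees, depth {∞, 8}, min leaf 1 |

The random-forest grid is small on purpose: every LOOCV tune fits
`n_train × |grid|` forests, and forests dominate the runtime of the whole
pipeline; on ~90-row datasets extra trees and leaf-size options did not
change selections enough to justify their cost.  The repeated benchmark
studies use further-thinned grids (`BENCHMARK_GRIDS`) with SVR ε fixed at
0.01 — ε must sit below typical titer differences (~0.05–0.25 au) or the
ε-insensitive loss ignores the signal; both arms of every contrast share
the same grids, so comparisons are unaffected.

Families are compared by mean ± sd test R² over 10 repeated stratified
90/10 splits, tuning from scratch inside every repeat (test rows never
enter any tuning fold).  For ranking, the default ensemble is linear +
kernel ridge on the complete dataset and all four families on the
producers dataset, both overridable.

## Training strategies and ranking

*One-time* training fits each family once on all rows.  *Recurrent*
training refits on 100 stratified 90% resamples, giving per-design
prediction spread; hyperparameters are tuned once per dataset and reused
across resamples (a per-resample retune flag exists, but retuning 100×
adds nothing on these sample sizes and two orders of magnitude of cost).

Every (family, resample) prediction vector over the full enumerated space
nominates its top-1, top-5 and top-10 designs (ties within a vector broken
by enumeration index, stable).  Frequencies are averaged within each
family first, then across families, so a 100-fit recurrent family and a
1-fit family carry equal weight.  The final order is lexicographic on
(freq_top1, freq_top5, freq_top10), then — because all designs outside the
nominated union tie at (0,0,0) — by ensemble mean prediction, then by
enumeration index.  The mean-prediction tie-break is what makes positions
outside the top group meaningful, e.g. when checking that measured
nonproducers rank near the bottom of the space.

Ranking quality is evaluated against measured data: the rank of the best
measured producer (BMP), of the five best producers, the rank
distribution of measured nonproducers, and the predicted relative
improvement of the top-10 designs over the BMP (against the ensemble's
own BMP prediction by default, so the comparison is like-for-like).

## Attribution

Both explanation tools work at **factor** granularity; per-column
shuffling or toggling would fabricate genotypes with zero or two active
levels of one factor.

*Permutation importance*: shuffle a factor's whole one-hot block across
samples and report the drop in R² from the unshuffled baseline
(mean ± sd over 10 permutations).  A single-level factor is constant and
scores exactly 0.

*Shapley values*: factors are players; the value of a coalition S is the
mean model prediction over a background population with the instance's
levels substituted on S.  Values are exact, enumerating all 2^F
coalitions (F ≤ 16; a seeded permutation-sampling estimator with
standard errors covers larger F).  Efficiency (Σφ = prediction −
background mean) holds to ~1e-12 and is asserted at 1e-9; symmetry and
null-player behaviour are tested on constructed models.  The background
defaults to the training designs, keeping hybrid designs in-distribution;
the full space is available via config.  Per-(factor, level) summaries
aggregate φ over the instances carrying that level.

*Expansion advice*: a factor is flagged "expand upward" when its
importance is positive and ≥ 50% of the maximum importance, and its most
positive mean-φ level uses the strongest promoter available for that
factor — the observed optimum sits at the boundary of tested expression,
so stronger expression or an additional gene copy is the natural next
design.  High-importance factors with an interior optimum are "keep";
the rest are neutral.

## Benchmark studies (problem sizes)

* **Recovery**: 20 simulated campaigns; each trains the recurrent
  complete-data ensemble (linear + KRR, 100 resamples) on 91 designs and
  asks whether the landscape's true best of 672 lands in the top 10 and
  where measured nonproducers rank.
* **Stratification contrast**: 20 paired repeats of both protocol arms
  at a 40% training fraction (36 designs ≈ 5.4% of the space), four
  families, thinned grids.  The repeats are spread over 5 independently
  simulated campaigns because the effect size varies strongly between
  landscapes; the study estimates the average effect, not one draw's.
  Even pooled, the gain (a few hundredths of R²) is comparable to the
  between-campaign spread, so per-family win counts at this problem size
  genuinely fluctuate between runs.
* **Attribution direction**: 10 campaigns whose landscapes give factors
  f4/f5 a dominant ±0.1 au expression ladder with the strongest buildable
  promoter best; success requires importance to rank those two factors
  first and Shapley to put their strongest-promoter levels most positive.

These sizes keep a full benchmark run in minutes on one CPU while leaving
each rate estimable to ~±10 percentage points.

## Known limitations

* Quantile strata and the uniform-sampling screen are stand-ins for
  unpublished details of the original workflow (clustering method,
  assembly bias); conclusions about those specifics cannot be drawn from
  this package.
* The LOOCV max-error tuner is O(n·|grid|) model fits; it is the right
  protocol for ~10²-row datasets but will not scale to 10⁴ rows.
* Exact Shapley is exponential in the number of factors; beyond 16
  factors only the sampling estimator is practical.
* R² on 9–10 test rows is noisy by nature; all evaluation reports carry
  sd over repeats for that reason.
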