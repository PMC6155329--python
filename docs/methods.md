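# Methods

## The model

`chromou` estimates adaptation and phylogenetic inertia in (log)
chromosome numbers with an Ornstein–Uhlenbeck (OU) model on a rooted
ultrametric phylogeny.  The response trait `y` (the species mean of
natural-log chromosome counts) evolves toward a *primary optimum* θ —
the value a lineage would equilibrate to if it stayed in its niche
indefinitely — with selection strength α and diffusion σ_y.  The two
reported natural parameters are

* the **phylogenetic half-life** `t_half = ln2 / α`, the time for the
  expected trait to move halfway from its ancestral value to the
  optimum, in units of tree height (all trees are rescaled to height 1
  before fitting, so `t_half = 0.25` means a quarter of the root-to-tip
  depth);
* the **stationary variance** `v_y = σ_y² / (2α)`, the equilibrium
  spread around the optimum, in squared log-count units.

On a unit-height ultrametric tree the tip covariance is

    V_ij = v_y · (1 − e^{−2α·s_ij}) · e^{−α·d_ij}

with `s_ij` the shared time from the root to the most recent common
ancestor and `d_ij` the patristic distance.  As `α → 0` with
`σ² = 2αv_y` held fixed this degenerates to the Brownian-motion (BM)
covariance `σ²·s`; as `α → ∞` it degenerates to white noise `v_y·I`.
Per-species observation variance (see below) is added to the diagonal.

Model variants share this covariance and differ in the mean:

* **intercept-only OU** — a single optimum; its half-life measures the
  overall phylogenetic effect in the trait.
* **BM** — no optimum, pure drift; the limit used as a yardstick for
  "phylogenetic effect entirely from inertia".
* **continuous-predictor OU** — the optimum is a linear function of a
  (BM-evolving) predictor.  The design column is attenuated by
  `ρ(α) = 1 − (1 − e^{−α})/α`; the fitted coefficient is the *optimal*
  slope (the relationship expected free of ancestral influence) and the
  across-species *phylogenetic* slope is `ρ` times it, hence never
  steeper.  Both are reported.
* **categorical OU (ANOVA)** — niches painted on branches select among
  K optima.  Tip i's expected value is a convex combination of the
  optima with weights given by its lineage's residence in each regime,
  discounted by `e^{−α·(time before present)}`; the root's residual
  weight `e^{−α}` is folded into the root regime's column, so no
  separate ancestral-state parameter is estimated and the design keeps
  K columns.
* **ANCOVA** — regime optima plus one attenuated continuous column
  (available, off by default in batteries).

### What the model omits

The full random-predictor OU regression carries an extra residual
variance term proportional to the squared slope times the predictor's
Brownian variance.  `chromou` uses the ρ-attenuated design with OU
residuals only.  Consequences: coefficient SEs for continuous models
can be mildly optimistic when the slope is large.  Predictor
measurement error (the per-species climate SDs the generator produces)
is likewise not propagated into the fit.

## Regime painting

Categorical predictors are observed at the tips and mapped onto
branches by minimum-change parsimony, implemented as unit-cost Sankoff
dynamic programming (identical to Fitch on binary trees and exact on
polytomies, which are accepted as-is).  The reported `change_count` is
the true parsimony minimum.  Ties are resolved deterministically: in
the top-down pass a node keeps its parent's state whenever that state
attains the node's minimum score, otherwise takes the alphabetically
first minimizer; at the root, ties between minimum-cost states go to
the state held by the most tips (pushing changes toward the tips,
DELTRAN-like), then alphabetical.  A shift is placed at the top of the
branch below the node where the state changes.

## Estimation

Fitting uses the classic two-level scheme: regression coefficients by
generalized least squares (GLS) at fixed `(t_half, v_y)`, and the
variance parameters by profile maximum likelihood:

* log-spaced grid over `t_half`, default 64 points in [0.01, 100] tree
  heights (configurable; results record the grid used);
* at each grid point `v_y` is maximized — in closed form
  (`v̂ = r'A⁻¹r / n`) when there is no observation variance, otherwise
  by bounded Brent search on [1e-8, 100·var(y)] with tolerance 1e-8.
  Fitting takes no random seed and is fully deterministic;
* the **support region** is the set of half-lives within 2
  log-likelihood units of the maximum.  Endpoints are interpolated
  linearly in log `t_half` between adjacent grid points, so the
  interval is nearly independent of grid resolution.  An MLE at the top
  of the grid is reported as `∞` (Brownian-like); a region touching the
  grid top gets an infinite upper bound; an MLE at the *bottom* of the
  grid is flagged as a boundary warning (no resolvable phylogenetic
  effect).  Exactly flat profiles (e.g. star trees) resolve to the
  smallest half-life — the weakest phylogenetic-effect claim.

`R²` is computed against an intercept-only GLS fit that reuses the
model's own covariance, `1 − (r'V⁻¹r)/(r₀'V⁻¹r₀)`, clipped to [0, 1].
AICc uses `−2ℓ + 2k + 2k(k+1)/(n−k−1)` with parameter counts fixed
package-wide: intercept-only OU = 3, BM = 2, continuous OU = 4,
categorical OU = 2 + K, ANCOVA = 3 + K.

Two Akaike-weight conventions are reported per battery: *global*
weights over all models, and *simple* weights over all models excluding
the single-equilibrium OU null (whose simple weight is blank).  The
latter convention is the one that reproduces published weight columns
of this analysis style; a literal pairwise-against-the-null variant is
available behind `simple_pairwise=True`.  A battery flags the predictor
that both attains the highest simple weight and reduces the half-life
relative to the null — the signature that part of the phylogenetic
signal reflects adaptation rather than inertia.

## Trait preparation

Responses are species means of natural-log counts (the log base is a
documented convention; it cancels in model comparison).  Within-species
replicate scatter is pooled across species,
`s²_pooled = Σ(nᵢ−1)s²ᵢ / Σ(nᵢ−1)`, and each species receives
observation variance `meᵢ = s²_pooled / nᵢ` (singletons get the full
pooled variance).  The basic number x is treated as a species constant
(majority rule on conflict, ties to the lowest value, with a logged
warning); observation variances are attached to the x response too by
default (`me_for_x=False` disables this).  Clade descriptive statistics
(mean, SD, CV = SD/mean) are computed across species means on the raw
count scale.  Ellenberg indicator values map onto habitat classes as
moisture dry[1–4]/moist[5–8]/wet[9–12], light forest[1–4]/
semi-shaded[5–8]/open[9–12] (the axis is inverted: high values = open),
nutrients oligo[1–3]/meso[4–6]/eutrophic[7–9].

## Synthetic data

The generator emulates the structure of an accession-level chromosome
count study on one clade: a unit-height Yule tree (dendropy's
birth–death sampler with tips extended by one extra exponential waiting
time so no terminal branch is zero), branch-wise Bernoulli regime
shifts (default probability 0.05 per branch, three habitat regimes —
simpler than a continuous-time Markov process but sufficient to
exercise parsimony mapping and the weight matrix), forward OU trait
simulation with the exact branch transition distribution, BM continuous
predictors with Gamma-distributed species SDs, and accession emission:
1–3 accessions per species, counts `exp(y + N(0, 0.05))` rounded to the
nearest even integer ≥ 4 (diploid counts are even by convention).
Default conditions — 132 species, `t_half = 0.25`, `v_y = 0.3`, optima
around `ln(25) ≈ 3.2` spanning ~1 log unit — mirror the magnitudes of
the real study system.  All generators are bit-reproducible given
(seed, config).

What the generator does *not* emulate: spatial climate rasters and
their extraction error, explicit polyploidy/dysploidy event processes,
taxon sampling bias, correlated predictors, and tree estimation error.
Passing recovery tests therefore demonstrates internal consistency of
the estimator under its own assumptions, not robustness to the
violations real data carry.

## Numerical choices and degenerate inputs

* Ultrametricity tolerance: relative 1e-6 of tree height; failing trees
  are rejected, never stretched.  Polytomies pass through everywhere.
* Covariances use `expm1` to avoid cancellation at small α; underflow
  at large α is harmless and suppressed.
* GLS solves via Cholesky whitening; rank deficiency is detected by
  pivoted QR and reported with the offending columns.  Grid points
  where the correlation matrix is numerically singular contribute −∞ to
  the profile rather than aborting the fit.
* Pagel's λ is maximized on [0, 1] by bounded Brent search (tolerance
  1e-6) with both endpoints checked explicitly; the upper bound is
  fixed at 1 for interpretability rather than the matrix-feasibility
  bound.  λ = 1 reproduces the BM likelihood exactly; λ = 0 the
  independent-observations likelihood.
* Fewer than 3 tips, constant responses (degenerate null residuals),
  negative observation variances, non-positive rates and zero-height
  trees raise informative errors.

## Problem sizes used by the test and acceptance runs

Recovery checks use 100 replicates of 200-tip trees for the
intercept-only model (median half-life and support-region coverage) and
100 replicates of 100-tip trees for the end-to-end categorical battery
(true habitat predictor vs. one categorical and one continuous decoy);
signal calibration uses 100-tip trees with a few hundred BM replicates.
These sizes give stable Monte-Carlo summaries while keeping a full run
in the low minutes on one core.

## Known limitations

Single α and σ for the whole clade (no niche-dependent rates of
adaptation); no Bayesian uncertainty on `(t_half, v_y)` beyond the
2-unit support region; non-ultrametric trees are out of scope; the
predictor-inflation variance term noted above is omitted; Fitch tie
resolution and shift placement are conventions, and alternative
reconstructions with equal parsimony scores would shift the painted
design slightly.
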