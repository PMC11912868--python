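# Methods

## Model

`selage` works with the expected site frequency spectrum (SFS) of a large
collection of unlinked sites evolving under the Wright–Fisher diffusion
with additive selection and recurrent mutation (the Poisson random field,
PRF, regime).  For a sample of `K = 2n` chromosomes, the expected spectrum
`Φ[i]` (`i = 1..2n−1`, the expected number of segregating sites at derived
count `i`) evolves one generation at a time,

    Φ^{t−1} = (I + Ξ_t) Φ^t + 2n μ_t δ₁ ,

where `t` counts generations before the present (down to `t = 0`), `Ξ_t`
combines genetic drift and selection in generation `t`, and the injection
term adds the expected sample singletons contributed by new mutations
(total mutation rate `μ_t` per generation across the site class).

**Drift.**  Projecting the diffusion onto binomial sample moments gives an
exactly tridiagonal generator with entries `(i−1)(K−i+1)/(4N)`,
`−2i(K−i)/(4N)`, `(i+1)(K−i−1)/(4N)`.  Its fixed point under singleton
injection is the classical neutral spectrum `θ/i` (`θ = 4Nμ`) *exactly*,
at any sample size — the first correctness anchor of the package.

**Selection.**  With per-copy selection coefficient `s` (heterozygote
`1+s`, homozygote `1+2s`, i.e. `h = 1/2`; deterministic change
`dx = s·x(1−x)` per generation), the moment equations couple the size-`K`
spectrum to the size-`K+1` spectrum.  The hierarchy is closed with an
order-3 jackknife: `Φ_{K+1}` is estimated from three consecutive entries
of `Φ_K` by assuming the underlying density of population frequencies is
locally quadratic.  The closure is *exact* for quadratic densities (unit
tested) and its overall accuracy is pinned by quadrature of the Wright
stationary density `∝ (1 − e^{−2γ(1−x)})/(x(1−x))`, `γ = 2Ns`: per-bin
agreement within 2% over the bins carrying 99.9% of the stationary mass,
for `|γ|` up to 100 at matched sample sizes.  The forward simulator uses
the identical `x' = x + s·x(1−x)` convention, so `γ` means the same thing
in every module.

**Operator structure and stability.**  The combined operator is banded
(bandwidth ≤ 3 off the diagonal; exactly tridiagonal when `s = 0`); it is
stored dense since `2n ≤ 250` in all intended uses.  Two regime limits are
enforced with warnings: the explicit one-generation update is stable only
for `2n < √(8N)` (the stiffest drift mode otherwise overshoots), and the
jackknife closure degrades once `|γ|` substantially exceeds the sample
size (warned at `|γ| > 4n`).  Expected counts that come out negative are
clipped when they are roundoff-scale (below 1e−12 of the spectrum's
maximum) and raise a `StabilityError` otherwise.

## Allele-age distributions

A mutation injected during the update that produces `Φ^{t−1}` has age
`a = t`; ages run `1..Tmax` and age 0 does not exist.  By linearity, the
cohort of age `a` contributes

    m_a = A_1 A_2 ⋯ A_{a−1} (2n μ_a δ₁),     A_t = I + Ξ_t,

to the present-day spectrum, and `Σ_a m_a = Φ⁰` holds to machine
precision.  The age density conditional on sample count `i` is
`P(a|i) = m_a[i] / Φ⁰[i]`.

Three routes compute these quantities and are cross-checked against each
other (agreement to 1e−6 or better) and against an exactly enumerated
small-population Markov chain (agreement to O(1/N)):

* **Backward (reference):** propagate the *destiny profile*
  `q_t = A_tᵀ q_{t−1}`, `q_0 = e_i`; then `m_t[i] = 2n μ_t q_{t−1}[1]`.
  This is the exact algebraic adjoint of the forward update, needs no
  linear solves, and is unconditionally stable.  (A pullback by inverse
  solves is algebraically tempting but amplifies the stiff modes of
  `A⁻¹` exponentially in `t`; it is numerically unusable beyond a few
  hundred generations and does not reproduce the exact-chain oracle.)
* **Equilibrium shortcut:** for constant `N, s, μ`, the steady-state
  spectrum is obtained by a direct linear solve (`−Ξ Φ = 2nμ δ₁`) and a
  single backward pass with one operator suffices.
* **All-frequencies:** the joint matrix `m[a][i]` for every `(a, i)` at
  once — a single-cohort power recurrence for constant histories, or one
  forward sweep propagating the transposed operator product for general
  histories.  The unconditional (pooled over `i`) density for an arbitrary
  history is obtained in O(Tmax) work by propagating the all-ones destiny
  vector.

`Tmax` is the computational horizon: `10·N` generations by default for
equilibrium models (a neutral allele still segregating after that is
negligibly probable); piecewise histories define their own horizon.  All
distributions are discrete over `a = 1..Tmax` and comparisons never
interpolate.

## Neutral-resampling approximation and divergences

For negative selection, the age distribution pooled over frequency classes
is well approximated by reweighting *neutral* conditional age densities
with the SFS ratio `w_i = P(i|γ)/P(i|0)` (both conditioned on
segregation; `μ` cancels).  `resampling_comparison` forms this
approximation and the exact counterpart (equal-class-weight pooling of the
selected conditionals, the convention under which the two coincide
exactly at `γ = 0`), and reports:

* base-10 KL divergence, evaluated with the resampling approximation as
  the sampling distribution, `Σ_a q(a) log₁₀(q(a)/p(a))` — the variant
  driven by the approximation's excess old-age mass, which is where it
  fails (most dramatically for positive selection, where the true ages of
  high-frequency alleles are far younger than neutral ones);
* total variation distance (half the ℓ1 norm, bounded in [0, 1]).

Probabilities are floored at 1e−300 inside logarithms only; no pseudo-mass
is ever added.  KL with a zero in the reference where the sampling
distribution has mass returns `inf` rather than raising.  Because the KL
at strong positive selection is dominated by log-ratios that grow linearly
with age in the deep tail, its value depends materially on `Tmax`; all
headline numbers are quoted at the `Tmax = 10N = 100,000` horizon.

The threshold arithmetic used throughout: a MAF cutoff `x*` implies the
critical strength `|γ*| = 1/(2x*)`; an unthresholded sample of `n`
diploids behaves like a cutoff at `1/(2n)`, hence `|γ*| = n`.

## Inference layer

PRF likelihood: `X_i ~ Poisson(Φ⁰[i|γ])` independently across bins; with
ages, `X_{ia} ~ Poisson(Φ⁰[i|γ]·P(a|i,γ))` (Poisson splitting).  Both the
split form (frequency Poisson × per-site conditional age terms, plus the
multinomial coefficient) and the product-of-cells form are implemented and
are numerically identical (1e−10), serving as a mutual check.  A MAF
threshold restricts the product to retained bins with unmodified means
(valid by bin independence).  Two conventions for the overall rate are
provided: total mutation rate known (default), or an analytic profile of a
common scale factor (`profile_theta=True`), which makes the likelihood
shape-only — the convention matched to segregation-conditioned Fisher
information and used in the replicate experiments, so that information
comes from frequencies and ages rather than from the number of sites.

Branch-averaged likelihood: when a site's age is known only up to an
interval `[a_b, a_e]` (a dated genealogical branch), the site's age term
becomes the average of `P(a|i,γ)` over the interval — uniformly over the
covered generations (`exact_grid`, deterministic, the default) or by `D`
uniform draws (`monte_carlo`, `D = 500` by default, seed required).  A
degenerate interval reproduces the exact-age likelihood identically.

Estimation minimizes the negative log-likelihood over `s` with bounded
Brent search (default bounds ±0.05; `γ̂ = 2N₀ŝ`).  A fit landing at a
bound is flagged.  The likelihood cache can snap evaluations to a quantum
on `s` (set well below the Monte Carlo spread of the estimates, e.g.
2e−5) so replicate fits on a shared template reuse each other's spectra.

Fisher information about `γ` is computed per site by central finite
differences (relative step `1e−3·max(1,|γ|)` on the `γ` scale, halved on
instability), using segregation-conditioned `P(i|γ)` for frequency-only
and the joint `P(a,i|γ)` for frequency+age; the information ratio is
compared with the ratio of replicate variances of the two estimators
(asymptotically equal).

## Simulator

Unlinked sites under the PRF regime: Poisson influx `2N_t μ_t` new
mutations per generation, each at one copy; deterministic selection
(`x' = x + s x(1−x)`) then binomial resampling of `2N` chromosomes; fixed
and lost alleles dropped; binomial subsampling to `2n` chromosomes at the
present, retaining sites segregating in the sample, with their true ages.
`tune_theta` uses linearity of the expected SFS in `μ` to hit a target
number of segregating sites (the experiments use ≈1,000 per replicate).
Validation: Watterson's expected segregating-site count, chi-square
goodness of fit of the sampled SFS against the expected-SFS recursion at
`γ ∈ {0, −5, −20, +5}`, and KS agreement of simulated ages with the
numerical age distributions both unconditionally and within frequency
classes.

The synthetic branch-interval generator attaches intervals of common
width `W = relative_width × mean(age)` containing each true age at a
uniformly random position.  The width is deliberately independent of the
site's own age: the probability of generating a given interval is then
constant across the ages it covers, which makes the interval-averaged
likelihood an exactly valid marginal likelihood — the property of dated
genealogical branches (age uniform along the branch, given the tree) the
generator emulates.  What it does *not* emulate: the systematic upward
stretch of branch dates estimated under a neutral prior for selected
alleles, and tree-reconstruction error; conclusions about those effects
require real tree inference, which is out of scope.

## What the experiments do and do not show

The replicate experiments (constant `N = 10,000`, `n = 100`, ~1,000 sites
per replicate, 30 replicates, horizons 6,000 and 2,500 generations for
`γ = −20` and `γ = −100` — long enough that the truncated age mass is
negligible at those strengths, and shared exactly between simulator and
likelihood) verify: unbiasedness of frequency-only and frequency+age
estimators; a modest full-SFS information gain from true ages at moderate
negative selection, with the replicate variance ratio tracking the Fisher
information ratio; a substantially larger gain when the spectrum is
thresholded at MAF ≥ 0.025 and `|γ|` exceeds `1/(2x*) = 20`; midpoint
point-estimates from wide intervals attenuating `γ̂` toward zero while
interval averaging removes that bias.  Because sites are unlinked and the
demography is known, these results quantify the information content of
ages under the model's own assumptions — not the additional uncertainty
of estimating ages from haplotype data.

Numerical conventions collected: discretization is one generation
everywhere (the diffusion-vs-discrete-Wright-Fisher gap is O(1/N, s) and
visible only as a ~1% CDF shift at `s = −0.01`, far below the weak-`s`
regimes of interest); tie-breaks and degenerate inputs (empty site tables,
zero-mutation histories, zero-width intervals, thresholds that empty the
data) raise typed errors (`ValidationError`, `StabilityError`,
`DegenerateHistoryError`) that the CLI maps to exit codes 2 and 3.
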