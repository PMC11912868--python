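# selage

**Allele-age distributions under selection, and how much ages add to
selection inference.**

`selage` is a Python library and command-line tool for population
geneticists who want to know how old a segregating variant is — given its
sample frequency, its selection coefficient, and a demographic history —
and how much statistical information allele ages carry about the strength
of (especially negative) selection beyond what the site frequency
spectrum already provides.

## What it computes

For a sample of `2n` chromosomes from a Wright–Fisher population with
piecewise history `N_t`, additive selection `s_t` (h = ½, scaled strength
`γ = 2Ns`) and mutation rate `μ_t`, the expected SFS `Φ[i]` evolves by a
one-generation banded moment operator (drift is exactly tridiagonal;
selection is closed by an order-3 jackknife):

```
Φ^{t−1} = (I + Ξ_t) Φ^t + 2n μ_t δ₁
```

Writing `m_a[i]` for the expected number of present-day sites at count `i`
that arose `a` generations ago (computed by stable adjoint/cohort
recursions), the package delivers:

* **Age densities** `P(a | i, γ, history) = m_a[i] / Φ⁰[i]` for one
  frequency or all frequencies at once, for arbitrary piecewise-constant /
  piecewise-exponential histories — no simulation, no Monte Carlo error.
* **Divergence diagnostics**: the neutral-resampling approximation
  (reweighting neutral age densities by the selected-to-neutral SFS
  ratio), with base-10 KL and total-variation distances quantifying when
  ages carry information beyond frequency (threshold: `|γ| > 1/(2·MAF)`).
* **Selection inference**: Poisson-random-field maximum likelihood for
  `γ` from frequencies alone, frequencies + true ages, MAF-thresholded
  spectra, or ages known only up to a genealogical branch interval
  (uniform interval averaging); plus Fisher-information and
  replicate-variance diagnostics of the information gain.
* **A Wright–Fisher forward simulator** of unlinked sites (paired
  frequencies and true ages, optional MAF thresholds and synthetic branch
  intervals) sharing the exact selection convention of the numerics.

## Worked example

```python
import numpy as np
from selage import (constant_model, joint_age_frequency, resampling_comparison,
                    SelectionLikelihood, fit_gamma, simulate_sites, tune_theta)

N, n = 1000, 20
neutral = constant_model(n=n, N=N, s=0.0, mu=1/(4*N))   # theta = 1, Tmax = 10N
selected = neutral.with_selection(-10 / (2 * N))        # gamma = -10

joint_s = joint_age_frequency(selected)
joint_0 = joint_age_frequency(neutral)
for i in (1, n):
    print(f"mean age | i={i:>2}: neutral {joint_0.conditional(i).mean():7.1f} gen, "
          f"gamma=-10 {joint_s.conditional(i).mean():7.1f} gen")

cmp = resampling_comparison(joint_s, joint_0)
print(f"neutral-resampling divergence at gamma=-10: "
      f"DKL = {cmp['kl']:.3f} (base 10), TV = {cmp['tv']:.3f}")

theta = tune_theta(selected, 1000.0)                    # ~1,000 segregating sites
sites = simulate_sites(selected, seed=1, theta=theta)
lik = SelectionLikelihood(neutral.with_mu_scaled(theta))
for mode in ("freq", "freq_age"):
    fit = fit_gamma(sites, lik, mode=mode, bounds=(-0.02, 0.02), profile_theta=True)
    print(f"{mode:>8} fit on {len(sites)} simulated sites: gamma_hat = {fit.gamma_hat:+.2f}")
```

prints

```
mean age | i= 1: neutral   330.5 gen, gamma=-10   114.2 gen
mean age | i=20: neutral  2630.9 gen, gamma=-10   653.7 gen
neutral-resampling divergence at gamma=-10: DKL = 0.417 (base 10), TV = 0.410
    freq fit on 963 simulated sites: gamma_hat = -10.03
freq_age fit on 963 simulated sites: gamma_hat = -10.08
```

Deleterious alleles at a given sample frequency are several-fold younger
than neutral ones (114 vs 330 generations for singletons at γ = −10), yet
the frequency-only and frequency+age fits recover γ almost equally well —
the SFS already carries most of the signal when every frequency class is
observed.  Ages become valuable once the spectrum is thresholded (e.g.
`fit_gamma(..., maf_min=0.025)`) and `|γ|` exceeds `1/(2·MAF)`.

The same computations are available from the shell:

```bash
selage agedist   --demography model.json --i 3 --out age.tsv
selage divergence --demography model.json --gammas -100,-20,0,20,100 --out div.tsv
selage simulate  --demography model.json --theta 400 --seed 7 --out sites.tsv
selage fit       --sites sites.tsv --demography model.json --mode freq_age --out fit.json
selage info      --demography model.json --gammas -50,-10,10,50 --out info.tsv
```

where `model.json` holds `{"sample_size_n": ..., "epochs": [...]}` (most
ancient epoch first; see `selage.popmodel.load_config`).

## Documentation

`docs/methods.md` describes the moment recursions, the jackknife closure
and its validity limits, the adjoint age algorithms and why they are the
numerically stable formulation, the likelihood conventions, the
simulator, and the design decisions behind each — together with what the
synthetic experiments do and do not demonstrate about real data.
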