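# lipoclust

Quantitative imaging and physical modeling of RNA–liposome nanoparticle
self-assembly.

When anionic RNA is mixed with cationic (DOTAP-type) liposomes, assembly
proceeds in two stages: RNA first adsorbs onto individual liposomes, and
the RNA-coated liposomes then cluster by diffusion-limited hit-and-stick
aggregation into structures ranging from sub-micrometer particles to
branched clusters tens of micrometers across. `lipoclust` is a toolkit
for analysing this process from two-channel fluorescence time-lapse
imaging and for simulating it with known ground truth. It is aimed at
researchers characterising lipoplex / RNA-nanoparticle formulations who
want per-particle, model-grounded statistics rather than ensemble
scattering averages.

## The models at its core

**RNA adsorption (initial stage).** Sequential irreversible adsorption is
modeled as a pure-birth process: a liposome holding *k* RNA molecules
acquires the next at rate λ₀(k+1). The population law at any time is then
geometric,

    P(n) = (1/(1+⟨n⟩)) (⟨n⟩/(1+⟨n⟩))ⁿ,   n = 0, 1, 2, …

— the discrete analog of an exponential RNA-per-liposome distribution —
with mean ⟨n⟩ set by the RNA-to-liposome ratio r₀/L₀. The same law is
the maximum-entropy distribution on the non-negative integers under a
mean constraint, so the prediction is model-independent in that sense.
A constant-rate variant (which gives a Poisson law instead) is kept as a
negative control.

**Cluster growth (second stage).** Aggregation follows the Smoluchowski
coagulation equation

    dn_k/dt = ½ Σ_{i+j=k} K_ij n_i n_j − n_k Σ_j K_kj n_j ,

with the Brownian encounter kernel
K(i,j) = (2/3)(k_BT/η)(R_i+R_j)(1/R_i+1/R_j) and fractal radius law
R_k = R₁k^{1/d_f}. Because this kernel is nearly size-independent, the
constant kernel K is an excellent approximation, and with x = t/τ,
τ = 2/(K n₀):

    n_k(t) = n₀ xᵏ⁻¹/(1+x)ᵏ⁺¹,  N(t) = n₀/(1+x),  ⟨k⟩ = 1 + x.

The scaled size law n_k/N is geometric with mean 1+x, so the cluster-size
and R_g distributions are dynamically scaling (time-invariant when scaled
by their means), and mean R_g grows as t^{1/d_f} at late times. The
package provides the closed form, a mass-audited truncated ODE
integrator, and the exact finite-population stochastic counterpart
(Marcus–Lushnikov process via the Gillespie algorithm), plus collapse and
power-law diagnostics.

**Patchy binding.** Cluster joining requires an RNA-coated (negative)
patch to meet a bare (positive) patch, so the sticking probability is
∝ f(1−f) in the fractional RNA surface coverage f: zero for bare
liposomes (f = 0), zero at saturation (f = 1), maximal at half coverage.
Applied as a multiplicative thinning of the aggregation kernel this
reproduces the observed non-monotonic dependence of growth rate on the
RNA-to-liposome ratio.

**Image quantification.** The measurement chain mirrors standard
fluorescence particle analysis: white top-hat + Gaussian filtering
(liposome channel) or rolling-ball background subtraction + Gaussian
(RNA channel), automatic global thresholding, connected components, and
per-feature metrics measured on the *original* raster: intensity-weighted
radius of gyration R_g, circularity 4π·area/perimeter², particles per
cluster k̂ = I/I_monomer, two-channel Pearson/Manders colocalization, and
the fractal dimension d_f from the mass–size scaling k ∝ R_g^{d_f}.

## Worked example

```python
import numpy as np
from lipoclust import smoluchowski as sm, adsorption as ad, patchy_binding as pb

# constant-kernel closed form, one growth time after mixing (x = 1)
state = sm.constant_kernel_solution(n0=1.0, K=1.0, t=2.0)
print(state.N, state.counts[0], state.counts[1])

# stochastic adsorption at RNA-to-liposome ratio 2
model = ad.AdsorptionModel(r0=2.0, L0=1.0)
res = ad.simulate_adsorption(model, n_liposomes=10_000, seed=1)
print(res.empirical_mean, np.mean(res.counts == 0))

# patchy-binding growth rates across surface coverage
for f in (0.1, 0.5, 0.9):
    rates = [pb.simulate_patchy(N0=2000, f=f, seed=s, t_end=4.0).rate
             for s in range(10)]
    print(f, round(np.mean(rates), 3))
```

prints

```
0.5 0.25 0.12500000000000003
2.0 0.3379
0.1 0.176
0.5 0.504
0.9 0.176
```

At x = 1 half the clusters remain (N/n₀ = 1/2) with monomer and dimer
fractions 1/4 and 1/8, exactly the closed form. The simulated adsorption
run stops at the target mean load 2 and leaves 33.8% of liposomes bare,
matching the geometric P(0) = 1/3. The growth rates trace k₀·4f(1−f)/2
(theory 0.18, 0.50, 0.18): doubling coverage from 0.1 to 0.5 nearly
triples the growth rate, while full coverage shuts assembly off again.

The same analysis runs end-to-end on images:

```bash
echo '{"t_max_tau": 8.0, "flux_liposome": 20000, "background_level": 50}' > gen.json
lipoclust generate --n-frames 10 --n0 600 --seed 7 --config gen.json --out bundle
lipoclust quantify --stack bundle/stack.tif --pixel-size 0.325 \
    --frame-interval 1.6 --time-start 1.6 --threshold-method triangle --out quant
lipoclust fit --summary quant/summary.csv --late-window 6 --out fit
```

The `fit` step prints (abridged)

```
"tau": 2.129, "n0": 515.2, "z": 0.288,
"N_fit_r2": 0.996, "powerlaw_r2": 0.907
```

The growth timescale recovered from the decay of the feature count,
τ̂ ≈ 2.13 min, matches the τ = 2 min used to drive the simulated
time-lapse within 7%; n₀ ≈ 515 of 600 monomers are detected (the
remainder are dim singles lost to thresholding or merged with close
neighbours). The image-measured growth exponent ẑ ≈ 0.29 underestimates
the truth-level exponent because the PSF sets a resolution floor on
R_g for the abundant small clusters; the truth-level checks in
`tests/test_acceptance.py` recover ẑ ≈ 0.4–0.5 against the theoretical
1/d_f = 0.5.

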