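# Methods

This note records the models implemented in `lipoclust`, their
assumptions, the parameter defaults and why they were chosen, and the
numerical decisions that a maintainer would otherwise have to reverse-
engineer from the code.

## Adsorption stage

RNA adsorption onto cationic liposomes is treated as a per-liposome
pure-birth (Markov counting) process: irreversible, sequential, with no
desorption. Two rate rules are implemented:

* **linear (default)** — a liposome holding k RNAs binds the next at
  rate λ₀(k+1). This is the minimal sequential scheme whose time-t
  population law is *exactly* geometric (verified in the tests against
  direct integration of the master equation
  dP_k/dt = λ₀[k·P_{k−1} − (k+1)·P_k]), matching the observed
  exponential RNA-per-liposome distribution. Whether the physical
  mechanism is literally (k+1)-proportional is not established; this
  scheme is the documented convention that reproduces the equilibrium
  law.
* **constant** — rate λ₀ independent of load, giving a Poisson law.
  Kept as a negative control: goodness-of-fit tests must *reject* the
  geometric law for it.

The stated equilibrium (mean load = r₀/L₀) is enforced by the stopping
rule: the merged, time-ordered event log is truncated at the first event
where the empirical mean reaches the target. Finite-RNA-pool accounting
is optional (default off) and caps total adsorption events at the
simulated subsample's share of the pool. Simulation exploits
per-liposome independence: waiting times are drawn in vectorized rounds
and merged, which is an exact sampling of the joint process.

The maximum-entropy cross-check solves the entropy maximization under
normalization + mean constraints through its exponential-family dual:
p_n ∝ exp(−βn) with β found by bracketed root-finding on the mean
(`brentq`, xtol 1e−13) over a support truncated where the geometric tail
mass falls below 1e−12. This is numerically exact to the truncation
level and avoids a high-dimensional constrained optimizer.

Intensity is assumed proportional to RNA copy number with an arbitrary
calibration factor; the mean-vs-ratio fit therefore reports a slope in
intensity units and tests only linearity and a zero intercept (95%
two-sided t test).

## Aggregation stage

Clusters merge pairwise and irreversibly; the suspension is well mixed
(no spatial structure). Three consistent routes are provided:

* **Closed form** (constant kernel, monodisperse start):
  n_k = n₀x^{k−1}/(1+x)^{k+1}, x = t/τ, τ = 2/(Kn₀). kmax is grown
  until the represented mass exceeds (1 − 1e−8)·n₀.
* **Truncated ODE**: LSODA with rtol 1e−10; gain terms are assembled
  with an anti-diagonal `bincount` over the kernel-weighted outer
  product, so arbitrary kernels cost O(kmax²) per right-hand side.
  Truncation is audited through mass conservation — coalescence
  products beyond kmax are dropped, which *shows up as mass loss* — and
  kmax doubles until the relative drift stays below 1e−6. This single
  audit catches both truncation and integrator error.
* **Stochastic (Marcus–Lushnikov)**: exact Gillespie simulation. Pair
  propensity K(k_a,k_b)/V; mass conservation is exact by construction.
  Size-independent kernels (constant, patchy-thinned) use an
  O(1)-per-event particle-list sampler (every pair equally likely);
  size-dependent kernels use the direct method over (i,j) size classes.

The Brownian kernel uses the standard fractal radius convention
R_k = R₁k^{1/d_f} (d_f ∈ (1,3]); its diagonal is exactly
(8/3)·k_BT/η independent of size, and within a size ratio of 2 the
off-diagonal values stay within 8% of the diagonal — the quantitative
justification for the constant-kernel approximation.

Time is kept in units of τ internally (volume = N₀ in the stochastic
runs gives τ = 2/K); wall-clock minutes enter only when fitting data.

**Growth fits.** τ̂ and n̂₀ come from nonlinear least squares of
N(t) = n₀/(1+t/τ); the growth exponent ẑ from log–log OLS of mean R_g
over a late-time window, default t ≥ 3τ̂ (the scaling prediction
R_g ~ t^{1/d_f} holds only once ⟨k⟩ ≫ 1). A window leaving fewer than
3 points is an error, not a silent fallback.

**Dynamic scaling.** The collapse diagnostic is the maximum pairwise
two-sample Kolmogorov–Smirnov distance between mean-scaled sample sets
(distribution-free, no binning choices). Two numerical realities inform
how it is applied to simulation output:

* simulated cluster sizes live on the integer lattice, while measured
  R_g is continuous; the k = 1, 2 atoms dominate the KS distance at
  early times. `sample_cluster_sizes(..., smooth=True)` therefore adds
  a U(−½, ½) jitter (the standard smoothed bootstrap for lattice data)
  before the radius mapping;
* collapse is a late-time property; the scaling checks sample the
  regime x = t/τ ∈ {6, 9, 12} where ⟨k⟩ ≫ 1.

With both in place the collapse statistic on constant-kernel runs sits
near 0.03–0.04 (n = 5000/time), while a shape mismatch as mild as
exponential-vs-uniform (closed-form CDF gap 0.153) stays above 0.15 when
sampled densely enough to resolve it.

**R_g change of variables.** P_R(R) = P_k(k(R))·dk/dR with
k(R) = (R/a)^{d_f}; discrete size laws are linearly interpolated onto
the continuum first, and the output is renormalized by trapezoidal
quadrature (tolerated drift 1e−6; a grid that misses >5% of the mass is
an error).

## Patchy binding

Coverage is a hard geometric footprint map
f = min(1, n·footprint/4πr²); excluded-area (RSA jamming) corrections
are deliberately not modeled, so f reaches 1 by construction. The
footprint (2×10⁻⁵ µm²) and liposome radius (0.05 µm) defaults are
calibration placeholders — mapping a mass ratio to coverage in real data
requires anchoring `calibration_ratio_at_half`.

The binding factor enters as a size-independent multiplicative thinning
of the kernel, K → K·4f(1−f) — the minimal well-mixed model consistent
with a growth rate proportional to the binding probability. The
normalized form 4f(1−f) (spanning [0,1]) is the default report; the raw
f(1−f) form is retained behind a flag since proportionality fixes only
the shape. Early-time growth rate is the slope of a linear fit of
⟨k⟩(t) over the first 20% of the run or until ⟨k⟩ = 3, whichever comes
first — with volume = N₀ the theoretical early slope is K·4f(1−f)/2, so
rate ratios across coverages are parameter-free (25/9 between f = 0.5
and f = 0.1).

## Synthetic imagery

The generator emulates epifluorescence fields of liposome clusters:

* cluster sizes geometric (the constant-kernel scaled law) or fixed;
* morphologies: straight chains (d_f = 1), hexagonally packed disks
  (d_f = 2), or off-lattice hit-and-stick growth for intermediate
  openness (random walkers launched from a surrounding circle, stepping
  `max(d/2, nearest − d)` and sticking at exact contact; candidate
  positions that would overlap a third monomer trigger a relaunch).
  The hit-and-stick mass–size exponent measures ≈1.65;
* PSF: isotropic 2-D Gaussian, σ = 0.3 µm default — adequate for
  epifluorescence at this scale, no Airy rings; pixel size default
  0.325 µm/px (a typical 20× sCMOS geometry; configurable);
* noise: Poisson shot noise on the photon image, then Gaussian read
  noise (sd 2 photons), over a 100-photon background plane with
  optional linear gradient. These defaults make thresholding
  nontrivial but solvable;
* placement: uniform with bounded rejection (1000 retries) against
  bounding-circle overlap, then a loud failure — silent overlap would
  corrupt the ground truth.

Scenes are 2-D only (the measurement chain analyses planes as 2-D
images); photobleaching, stage drift and 3-D PSFs are out of scope.
Passing tests on this imagery therefore demonstrate correctness of the
measurement chain under a *known, idealized* forward model; they do not
certify performance on real data with aberrations, uneven illumination,
or depth-dependent blur.

An important exact property used throughout: an isotropic Gaussian PSF
adds σ² of variance *per axis*, so the 2-D radial radius of gyration
broadens as R_g,meas² = R_g,true² + 2σ². Reported per-feature R_g is
always the raw intensity-weighted value; ground-truth comparisons and
the fractal-dimension fit de-broaden analytically with this relation
rather than deconvolving images.

## Measurement chain

Filter sequence is fixed (top-hat → Gaussian for the liposome channel;
rolling ball → Gaussian for the RNA channel); radii are conventions:
top-hat disk radius 5 px, Gaussian σ 1 px, rolling ball 15 px. The
global automatic threshold defaults to Otsu but is a config tag:
Otsu's between-class split is well suited to a single bright object but
drops dim monomers in fields that also contain much brighter clusters,
so the sparse-field calibration analyses use the triangle method
(`threshold_method="triangle"`). Connectivity 8 and a 4-px minimum
feature area suppress single-pixel noise. Intensities are measured on
the original raster restricted to the mask; the filtered images make
masks only. Features touching the frame border are flagged and excluded
from R_g statistics (truncation bias), and every exclusion is counted
in the per-frame summary.

The particles-per-cluster estimator k̂ = I/I_monomer requires a
calibration population; `estimate_monomer_intensity` averages features
with R_g below a monomer cutoff. The fractal-dimension fit (OLS of
log k̂ on log R_g) exposes `kmin` because small clusters sit below the
asymptotic mass–size scaling: hexagonally packed disks only reach
k ∝ R_g² above k ≈ 8, and the fit demands a ≥4× dynamic range in R_g
before the slope is considered identifiable. With PSF de-broadening and
these windows, rendered chains fit d_f ≈ 0.96 and rendered disks
d_f ≈ 2.0.

Colocalization: Pearson over a mask or the full frame (flagged
undefined for a constant channel); Manders fraction A is the share of
channel-A intensity where channel B exceeds its own Otsu threshold.
Note that for spot-like (Gaussian) objects a fraction of true signal
always lies below threshold in the tails, so Manders = 1 is attained
only for flat-topped objects.

## Problem sizes

The statistical checks run at sizes chosen to separate signal from
Monte-Carlo noise while staying lightweight: 200 replicates of N₀ = 1000
for the stochastic/analytic ensemble comparison (3-SE bands);
10⁴ liposomes for adsorption goodness-of-fit at α = 0.01;
N₀ = 70 000 monomers for the collapse check (≥5000 clusters at the
latest time, n = 5000 samples per time); 50 replicates of N₀ = 2000 per
coverage point for the growth-rate reversal; and a few 512² rendered
fields per quantification check.

## Known limitations

* The (k+1)-proportional adsorption rate is a convention reproducing
  the geometric law, not a derived mechanism; electrostatics, RNA
  conformation and desorption are not modeled.
* Patchy thinning is size-independent and well mixed; spatially
  resolved (Brownian-dynamics) aggregation is not implemented.
* No gelation-prone kernels, fragmentation, or 3-D segmentation;
  clusters are not tracked across frames (analyses are per-frame
  distributions).
* Image-measured growth exponents are biased low when monomer-scale
  features dominate, because the PSF floors their R_g; truth-level
  analyses (or de-broadened statistics) should be used when the
  exponent itself is the quantity of interest.
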