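# Methods

## Synthetic blastoderm cohorts

The generator emulates the data structure of quantitatively imaged,
fluorescently stained blastoderm embryos: per embryo, expression averaged
into 100 bins along the AP axis (bin centers 0.5 … 99.5 %EL, anterior = 0),
with a lacZ reporter channel, an *hkb* costain channel, and a cohort-averaged
Bcd channel.

**Bcd gradient.** Modeled as a single exponential, `exp(−ap/λ)` with
λ = 20 %EL by default. The exponential form and λ are modeling choices
(standard values from the gradient literature), not measured here; both are
configurable. Per-embryo gradients carry small multiplicative lognormal
noise (CV 0.1 by default — the gradient is highly reproducible embryo to
embryo); the bin-wise mean over the cohort is rescaled to maximum 1 and is
the concentration standard for all downstream analysis, so gMM values are in
units of the unit-max averaged profile.

**Reporter and costain.** Per embryo *e* and bin:

    lacZ(ap) = (A_e · G(bcd_avg(ap)) + b) · η(ap)
    hkb(ap)  = plateau(ap) · η′(ap)

with truth GRF `G` (a Hill function or any callable), embryo amplitude
`A_e = exp(N(0, amp_sd))` (staining efficiency varies between embryos),
additive staining background `b`, unit-mean lognormal per-bin noise η with
CV `noise_cv`, and an *hkb* plateau at `costain_level` in the posterior 10%
of the axis (a dim 10% nonspecific baseline elsewhere). The truth GRF is
evaluated on the averaged Bcd profile — the same standard the analysis
pairs against — so the noise-free pipeline recovers the truth exactly (up
to the minimum-subtraction truncation below).

**What the generator does not emulate:** 3-D nuclear geometry and
segmentation error, dorsoventral structure, batch-to-batch staining
chemistry, developmental-time drift within nuclear cycle 14, and spatially
correlated noise. Passing tests therefore validate the analysis logic and
its statistical behavior under realistic amplitude/bin noise, not the
imaging pipeline itself.

## Trace processing

Background is removed by subtracting the minimum along the axis. A
consequence worth knowing: with a Hill truth the posterior-most bin still
carries a tiny signal, so min-subtraction removes background plus
`G(bcd_min)`; for boundaries interior to the axis this truncation is below
1e−6 of Emax and the noise-free pipeline recovers Hill parameters to that
accuracy. Staining intensity is normalized by the 95% quantile (linear
interpolation between order statistics) of *hkb* over bins with
ap ≥ 90 %EL; a non-positive normalizer is an error naming the embryo. GRF
samples pair each lacZ bin with the averaged Bcd value of the same bin,
optionally restricted to an AP window (default: full axis).

## Hill fitting

Per-embryo unweighted least squares (`scipy.optimize.least_squares`, TRF)
of `E = Emax·b^nH/(Ka^nH + b^nH)`. Initialization: Emax = max(expr), nH = 4,
Ka = Bcd of the sample nearest half-max. Bounds: nH ∈ [0.5, 20],
Ka ∈ [1e−4, 10], Emax ∈ (0, 10·max]. Inputs that cannot identify three
parameters (fewer than 5 distinct Bcd values, flat expression, no half-max
crossing) are rejected explicitly. Cohorts are summarized as mean ± sample
SD (ddof = 1) over converged fits; non-converged fits are excluded and
counted. The ± throughout is SD across embryos, not SEM.

## Position and steepness

On an averaged GRF: `Bcd05` is the smallest Bcd at which the linearly
interpolated, Bcd-sorted expression crosses half its maximum (first
crossing, a deliberate convention for non-monotone averages). The
derivative of the max-normalized expression is estimated by central
differences (`numpy.gradient`) on the Bcd-sorted samples; `rS` is its
maximum and `rP` the Bcd there, ties breaking toward smaller Bcd. Then
P = rP/Bcd05 and S = rS·Bcd05.

**Finite-difference spacing floor.** Because the Bcd axis itself is a noisy
measurement, sorting by Bcd leaves near-duplicate concentrations adjacent,
and a central difference there divides pure expression noise by a vanishing
increment — in noisy cohorts this produced steepness estimates an order of
magnitude above truth. Samples closer than 0.025 in ln(Bcd) (half the
nominal per-bin spacing 1/λ of the 100-bin format) are pooled by averaging
before differencing. Exact-math checks on clean dense grids disable the
floor (`min_log_spacing=0`). No other smoothing is applied; half-cohort
averaging is the noise suppression mechanism.

**Uncertainty.** Per condition, 100 random subsamples of ⌈n/2⌉ embryos
(without replacement, seeded) are averaged and reduced to (P, S). A 2-D
product-Gaussian KDE with per-dimension Silverman bandwidth
(h_j = σ_j·n^(−1/6), the d-dimensional Gaussian-optimal rule at d = 2) turns
the subsample cloud into a density; the p-value against a model region is
the fraction of 1e5 seeded draws from the Gaussian mixture that fall inside
the region (standard error reported). A degenerate cloud (all points equal,
e.g. noise-free cohorts) is reported as plain point membership.

## Equilibrium model

One activator binding n sites plus one polymerase site: 2^(n+1)
microstates. Weight of (bound set B, Pol state p):

    w = x^|B| · Π_{i∈B} K_i · Π_{S⊆B, |S|≥2} ω(S) · [p=1: q · Π_{S⊆B, S≠∅} γ(S)]

The GRF f(x) = Σ Pol-bound weights / Σ all weights is rational of degree n.
One free factor per subset is the fullest equilibrium parameterization
(each microstate gets one free energy); the `pairwise_tf_tf` mode frees
only pair ω and singleton γ (an activator must contact Pol somehow), and
`pairwise_tf_pol` only singleton γ. Bare K_i and q are sampled from the
same 10^U[−3,3] law as the HOCs: position normalization removes the overall
concentration scale but relative site affinities matter.

**Numerics.** Coefficients are stored as natural logs: with up to 127
sampled factors of 10^±3, linear coefficients overflow float64 by hundreds
of orders of magnitude, while all ratios stay well conditioned. For shape
computation the concentration is rescaled to y = x/Bcd05 and coefficients
divided by D(Bcd05), which maps the denominator coefficients into (0, 1]
(they sum to 1); the derivative numerator E = M′D − MD′ with
M = N − f(0)·D (whose constant term is exactly zero) is then formed in
plain linear arithmetic — no cancellation of exponentials. Bcd05 comes from
bisection on a ±60-decade log grid; the derivative is maximized on a
601-point grid spanning ±6 decades around Bcd05 with golden-section
refinement, so P and S read off directly in y units. Affine normalization
F = (f − f(0))/(f(∞) − f(0)) maps endpoints to 0 and 1; draws with
f(∞) − f(0) ≤ 1e−9 are non-activating and rejected.

## The achievable region

`compute_region` samples parameter sets, computes shapes, and bins P over
the occupied range (200 bins by default) recording per-bin min/max
steepness envelopes; membership tests interpolate the envelopes linearly
between occupied bin centers. Envelopes rather than a hull because the
region need not be convex.

**Which draws delimit the region.** The region delimits *boundary-forming*
GRFs — the objects the shape coordinates were designed for and the only
ones comparable to measured expression boundaries. Three classes of
responsive draws are excluded, each counted in the region metadata:

1. *Non-monotone* GRFs (`n_nonmonotone`): mixed-sign TF–Pol couplings can
   make f rise and fall (e.g. rise 0.71, fall 0.71, net range 0.0016);
   affine normalization by the tiny net range then yields arbitrarily large
   "steepness" that measures the transient spike, not a boundary.
2. *Multi-scale staircases* (`n_multistep`): monotone GRFs rising in
   well-separated steps. The absolute derivative of an early small step at
   concentration scales far below Bcd05 is unboundedly amplified by the
   1/Bcd normalization. Detected as a non-unimodal derivative profile
   dF/dy over the shape grid (strict tolerance 1e−6 of the peak; structure
   hiding below the grid surfaces as an elevated derivative plateau at the
   low edge, since dF/dy tends to the normalized linear coefficient as
   y → 0), plus a coarse log-slope unimodality screen on the wide grid.
3. *Hyperbolic-type* GRFs (`n_hyperbolic`): concave mixtures of hyperbolas
   whose derivative is maximal in the y → 0 limit; they form no inflected
   boundary at all, and scale-separated mixtures again have unbounded S.
   When the entire model class is hyperbolic — one binding site, where
   every responsive draw normalizes exactly to y/(1+y) — the region
   degenerates to the point (0, 1) and is built from those draws
   (`hyperbolic_fallback`).

Under these screens the sampled envelopes reproduce the expected geometry:
the n-site full-HOC upper envelope meets the Hill-n point (e.g. envelope
1.542 vs closed form 1.5425 at n = 6 with 1e5 draws), regions nest in site
count and in cooperativity mode, and pairwise-only modes stay below the
Hill-6 steepness in the sharp-boundary position range — TF–Pol pairwise
far below (≈0.85), TF–TF pairwise approaching but not attaining it, since
its all-or-none limit is exactly a Hill-n GRF.

**Estimator noise.** The per-bin maximum of a thin-tailed steepness
distribution converges slowly; below P ≈ 0.3 the envelope is set by rare
strongly asymmetric near-hyperbolic draws and fluctuates at 1e5 draws.
Envelope comparisons (nesting, exponent-range stability) therefore probe
the densely sampled sigmoid band P ≥ 0.3, which contains the measured
shapes (P ≈ 0.9). Widening the sampling exponents from [−3, 3] to [−4, 4]
changes the 6-site envelope by ≈5% median over that band, i.e. the
boundary has essentially stabilized.

## Pipeline defaults and problem sizes

Cohorts: 6–11 embryos (matching imaged cohort sizes per condition),
noise_cv 0.05–0.08, amp_sd 0.1, background 0.1. Shape uncertainty: 100
half-cohort subsamples; KDE integration 1e5 draws. Regions: 2e5 draws for
n = 6 by default (1e5 in the test suite), 200 position bins (25 in tests,
where per-bin occupancy matters more than resolution). All stages are
seeded; every artifact carries the config hash and seeds.

## Limitations

- The equilibrium region is a sampled envelope, not a proof-based boundary;
  tail regions (P < 0.3) are under-sampled by design of the draw law.
- The per-subset HOC basis spans all equilibrium models, but the sampling
  *measure* over GRF shapes differs between parameterization bases; region
  interiors are comparable, fine envelope detail is basis-dependent.
- Hill fits carry a small downward nH bias (≈2–4% at the default noise)
  from minimum subtraction and noise-induced flattening; recovery tests
  budget for it.
- No non-equilibrium (energy-expending) models: steady-state mRNA is
  proportional to Pol-bound probability, with degradation folded into the
  proportionality constant.
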