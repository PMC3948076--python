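# Methods

## Decay model and reconvolution

A pixel's (or cell's) TCSPC histogram collects photon micro-times —
arrival times relative to the excitation pulse — into B equal bins over
the repetition window T (default T = 25 ns, the period of a 40 MHz
pulsed laser; B = 256). The fluorescence impulse response is a 1–3
component multi-exponential

    I(t) = Σᵢ αᵢ exp(−t/τᵢ),   αᵢ ≥ 0 counts/ns,  τᵢ > 0 ns,

and the expected histogram is I convolved with the instrument response
function (IRF), integrated per bin, plus a constant baseline. Because
slow components have not fully decayed when the next pulse arrives, the
convolution is *circular* over T: the geometric sum over previous
pulses folds into a closed-form factor 1/(1 − e^(−T/τ)) per component.
This wrap term is on by default and switchable (`wrap=False`).

Numerically, each bin is subdivided (oversampling 16×); the decay
density is integrated *exactly* over each fine cell (the exponential is
discontinuous at the excitation instant, where midpoint sampling would
be first-order accurate), the IRF kernel is sampled at fine-grid points
so the discrete circular convolution pairs cell averages with exact
center-to-center lags, and products are accumulated by FFT. Against a
direct-summation oracle on a 64× grid the forward model agrees to
better than 1e-4 relative; with a delta IRF at zero offset an analytic
per-bin expression is used instead.

IRF kinds: parametric Gaussian (center, FWHM; default FWHM 0.3 ns —
typical for a diode laser + SPAD detection chain), ideal delta, or a
measured histogram (normalized to unit area and regridded by linear
interpolation; a window mismatch raises a regrid-required error rather
than silently rescaling the time axis).

## Fitting

The default objective is the Poisson negative log-likelihood
Σ(m − c·log m) — counts are photon counts, so this is the statistically
correct choice; weighted least squares with weights 1/max(c, 1) is the
alternative. Optimization is bounded L-BFGS-B on log-lifetimes and
log-amplitudes (τ ∈ [0.01, 50] ns), with a documented multi-start:
lifetime starts on a log-spaced grid over [0.1, 10] ns (all k-subsets
for k components), amplitudes initialized by non-negative least squares
against the unit-amplitude component curves, best final objective wins,
near-ties resolved toward the first (smaller-τ₁) start. A stalled
optimizer returns `converged=False` instead of raising. Reported
goodness of fit is the Pearson χ² per degree of freedom.

Histograms below the photon threshold (default 500 photons, inclusive:
exactly 500 survives) are refused; in whole-field fitting such pixels
are flagged absent (NaN), never zero. Two-component fits whose fitted
lifetime ratio falls below 1.5 raise an `IdentifiabilityWarning` and
set a flag — closer pairs are not reliably separable at realistic
photon budgets.

"Average lifetime" defaults to amplitude weighting Σαᵢτᵢ/Σαᵢ;
intensity weighting Σαᵢτᵢ²/Σαᵢτᵢ is exposed. Both the number of
components and the weighting are configuration choices, since a single
reported "average lifetime" does not determine them.

## FRET analysis

Efficiency is the donor-quenching form E = 1 − τ_DA/τ_D. Mean
efficiency strictly above 0.05 is classified significant ("above 5%":
the boundary itself is not significant). Negative efficiencies
(apparent lifetime lengthening) are reported, not clipped — they are
diagnostic of registration or staining problems.

Per-cell efficiencies are computed for each donor+acceptor cell against
the donor-group *mean* lifetime and then averaged (the published
group-level efficiency ranges are not exactly the group-mean ratio, so
per-cell averaging is the default; the group-means estimator is exposed
as an option). The group p-value is a two-sided two-sample Student
t-test on the raw lifetime samples (equal variance by default, Welch
optional). Both groups must contain at least 25 cells; smaller samples
require an explicit override.

## Co-localization

Pearson's r is the product-moment correlation of the two channels over
the pixels of one nucleus mask; zero-intensity pixels inside the mask
are included (no exclusion rule is imposed), and a constant channel is
an error, not r = 0. Manders' M1 is the fraction of channel-A intensity
on pixels where channel B exceeds its threshold (default 0, i.e. any
strictly positive intensity), M2 symmetric; sums are restricted to the
nucleus mask. Automated threshold search (Costes) and object-based
co-localization are out of scope; analysis is 2-D, per plane.

Nucleus selection keeps ROIs whose equivalent diameter (from mask area
and pixel size) lies within ±10% (inclusive) of a reference diameter;
when no reference is supplied it is estimated as the modal equivalent
diameter (densest histogram bin, median below n = 4). Group summaries
are mean ± SEM over nuclei; a single nucleus reports no SEM. Group
comparison: Student's t-test for two groups, one-way ANOVA otherwise;
exactly-equal degenerate samples are reported as statistic 0, p = 1.

## Synthetic data

The decay simulator draws each photon's component by photon share
αᵢτᵢ, adds an exponential waiting time and the IRF jitter, and wraps
modulo T — producing *exactly* the wrapped density the forward model
integrates, so fits of simulated data test the estimator, not a model
mismatch. Photon counts are conserved exactly and every generator is
byte-deterministic under its seed.

The image simulator places non-overlapping disk nuclei (default 7 μm ±
0.5 μm jitter, 0.1 μm/px so sub-0.3 μm puncta span 1–3 px). Channel A
holds heterochromatin-like aggregates: per nucleus, 10 disks with
diameters uniform in (0.5, 1.5) μm, mutually separated by ≥ 2 px so
their rasterized components remain measurable (a d-μm disk on a 0.1 μm
grid carries about half-a-pixel quantization, which is why the size
check in the tests allows one pixel pitch of slack). An independent
pattern holds ~120 euchromatin-like fine puncta. Channel B is the
mixture ρ·norm(A-pattern) + (1−ρ)·norm(puncta) — an interpretable,
monotone link from the ground-truth mixing level ρ to measured r,
without claiming a closed form r(ρ) under noise. A DAPI-like third
channel combines aggregates with the nucleoplasm base (intensity 0.1;
compartment intensity ratios are free parameters since no measured
ratios exist to copy). Gaussian PSF blur (σ = 0.1 μm, i.e. FWHM ≈
0.24 μm, a high-NA confocal) precedes Poisson shot noise at the photon
budget (default 200 photons at unit intensity) and Gaussian read noise
(SD 2) — the photon-limited imaging order. Disk centers are uniform
over the whole nucleus area: restricting them to the interior gives
both channels a shared dark rim and biases r upward at ρ = 0.

What the generator does *not* emulate: real antibody staining
statistics, tissue autofluorescence, z-stacks, chromatic aberration,
segmentation errors (label masks are ground truth). Passing tests
therefore demonstrate the correctness of the estimators and pipelines
under the stated model, not robustness to those real-data effects.

## Problem sizes and numerical choices

Simulation-backed tests use 25 replicates × 10,000 photons for lifetime
recovery (and one 100-replicate bias/coverage check), 10 seeded fields
per mixing level at 160² px with 2 nuclei for the monotonicity sweep,
and 200 fast-mode replicates for the null false-positive bound — sizes
at which the checked tolerances are comfortably resolved. The fast mode
of `simulate_fret_pair` draws per-cell lifetimes from
Normal(τ, 0.05 ns) directly (0.05 ns is the replicate SD observed for
full decay fits at 10,000 photons); the full mode simulates and fits
real decays, and the two are cross-validated against each other in the
suite.

Ties and degenerate inputs: histogram bins are half-open with the last
bin closed; background subtraction clips at zero and copies its input;
the empty field returns empty maps rather than erroring; the
delta-IRF path is exact, so the reconvolution limit check is analytic.
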