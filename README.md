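# flimcoloc

Quantitative analysis of differential chromatin binding measured by
two complementary fluorescence-microscopy readouts:

* **FLIM-FRET** — time-correlated single photon counting (TCSPC) decay
  histograms are fitted by multi-exponential *reconvolution* against an
  instrument response function (IRF); a donor fluorophore whose binding
  partner (acceptor) sits within Förster distance (< ~10 nm) is
  quenched, and the efficiency of that energy transfer is
  `E = 1 − τ_DA/τ_D`, with `τ_D` the donor-only lifetime and `τ_DA` the
  donor lifetime in the presence of acceptor. A mean efficiency above
  5% over ≥ 25 cells counts as a genuine molecular interaction.
* **Per-nucleus co-localization** — Pearson's coefficient `r ∈ [−1, 1]`
  and Manders' overlap coefficients `M1, M2 ∈ [0, 1]` computed per
  nucleus ROI over two channels, with nucleus selection (±10% of a
  reference diameter), group mean ± SEM over ~20 cells, and Student's
  t-test / one-way ANOVA group comparisons.

The decay model is `I(t) = Σᵢ αᵢ exp(−t/τᵢ)` (1–3 components),
circularly convolved with the IRF over the 25 ns repetition window of a
40 MHz pulsed laser and fitted by Poisson maximum likelihood — the
correct objective for photon-counting data. Pixels below 500 photons
are excluded.

Because no raw microscopy is bundled, a first-class `synthetic` module
generates both data kinds with known ground truth: Poisson photon
decays at chosen lifetimes, and two-channel nuclear images with
DAPI-dense heterochromatin aggregates (0.5–1.5 μm) versus DAPI-sparse
euchromatic puncta (< 0.3 μm) at a controllable true co-localization
level ρ.

## Worked example

```python
import numpy as np
from flimcoloc import (DecayModel, IRF, SyntheticDecaySpec,
                       simulate_decay, fit_decay, fret_efficiency,
                       analyze_fret_experiment, simulate_fret_pair)

# --- lifetime fitting: simulate a 2.45 ns donor decay and refit it
irf = IRF(kind="gaussian", center_ns=1.0, fwhm_ns=0.3)
spec = SyntheticDecaySpec(model=DecayModel(components=[(1.0, 2.45)]),
                          irf=irf, n_photons=10_000, seed=1)
fit = fit_decay(simulate_decay(spec)[0], irf)
print(f"fitted tau = {fit.tau_mean_ns:.3f} ns (chi2_r = {fit.reduced_chi2:.2f})")
# fitted tau = 2.442 ns (chi2_r = 0.84)

# --- FRET: donor-only vs donor+acceptor lifetimes
print(f"E = {fret_efficiency(2.45, 2.17):.4f}")
# E = 0.1143
donor, da = simulate_fret_pair(2.45, 2.17, n_cells_each=30, seed=2)
res = analyze_fret_experiment(donor, da)
print(f"mean E = {res.mean_efficiency:.4f}, significant = {res.significant}, "
      f"p = {res.p_value:.2e}")
# mean E = 0.1081, significant = True, p = 3.39e-28
```

The fitted lifetime recovers the simulation truth to within the photon
shot-noise limit; the efficiency of the 2.45 → 2.17 ns pair is 11.4%,
well above the 5% interaction rule, and the 30-cell group comparison
rejects equal lifetimes decisively.

A command-line interface mirrors the library
(`flimcoloc simulate-image | simulate-decay | fit | fret | coloc | run`);
exit codes are stable (0 ok, 2 config, 3 data, 4 sample size).

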