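"""Multi-exponential reconvolution fitting of TCSPC decay histograms.

The decay model is I(t) = sum_i alpha_i * exp(-t / tau_i): each
component contributes an exponential with amplitude ``alpha_i`` (a rate
in counts/ns at t = 0) and lifetime ``tau_i`` (ns). The expected decay
curve is this model convolved with the instrument response function
(IRF) and integrated over the histogram bins, plus a constant baseline.
Because the laser re-excites every 25 ns before slow components have
fully decayed, the convolution is circular over the repetition window
(one wrap term resummed in closed form); this can be switched off.

Fitting maximizes the Poisson likelihood of the observed counts by
default — the statistically appropriate objective for photon-counting
data — with a weighted-least-squares alternative. Initialization is a
documented multi-start: lifetimes from a log-spaced grid, amplitudes
from a non-negative linear solve at fixed lifetimes, best final
objective wins.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import (
    ConfigError,
    DataError,
    IdentifiabilityWarning,
    InsufficientPhotonsError,
    RegridRequiredError,
    UndefinedMeanError,
)
from .tcspc import (
    DEFAULT_PHOTON_THRESHOLD,
    DecayHistogram,
    IRF,
    PhotonRecord,
    bin_photons,
)

_TAU_BOUNDS = (0.01, 50.0)
_MIN_TAU_RATIO = 1.5  # below this, neighbouring lifetimes are not separable


@dataclass
class DecayModel:
    """A 1–3 component multi-exponential decay.

    ``components`` is a list of ``(alpha, tau_ns)`` pairs kept sorted by
    ascending lifetime. ``baseline`` is a constant background in
    counts/bin; ``shift_ns`` is the IRF-to-signal time offset.
    """

    components: list[tuple[float, float]]
    baseline: float = 0.0
    shift_ns: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 3:
            raise ConfigError("model must have 1 to 3 components")
        for alpha, tau in self.components:
            if alpha < 0:
                raise ConfigError(f"negative amplitude {alpha}")
            if tau <= 0:
                raise ConfigError(f"non-positive lifetime {tau}")
        if self.baseline < 0:
            raise ConfigError("baseline must be non-negative")
        self.components = sorted(self.components, key=lambda c: c[1])

    @property
    def alphas(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for _, t in self.components])


@dataclass
class FitResult:
    """Outcome of one decay fit."""

    model: DecayModel
    tau_mean_ns: float
    reduced_chi2: float
    converged: bool
    n_photons_used: int
    objective: str = "poisson-mle"
    identifiability_flag: bool = False


def mean_lifetime(model: DecayModel, weighting: str = "amplitude") -> float:
    """Average lifetime of a multi-exponential model.

    ``amplitude`` weighting returns sum(a_i t_i)/sum(a_i); ``intensity``
    weighting returns sum(a_i t_i^2)/sum(a_i t_i) (each component
    weighted by its photon share rather than its initial rate).
    """
    a, t = model.alphas, model.taus
    if np.sum(a) <= 0:
        raise UndefinedMeanError("all amplitudes zero: mean lifetime undefined")
    if weighting == "amplitude":
        return float(np.sum(a * t) / np.sum(a))
    if weighting == "intensity":
        return float(np.sum(a * t * t) / np.sum(a * t))
    raise ConfigError(f"unknown weighting {weighting!r}")


# ---------------------------------------------------------------------------
# forward model


def _check_edges(bin_edges: np.ndarray) -> np.ndarray:
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ConfigError("bin_edges must be 1-D and strictly increasing")
    return edges


def _irf_fine_kernel(
    irf: IRF, window_ns: float, n_fine: int, shift_ns: float
) -> np.ndarray:
    """IRF as a unit-sum kernel on the fine circular grid.

    Sampled at grid points j*dt so that the discrete circular
    convolution with cell-averaged densities pairs the kernel with
    exact center-to-center separations (second-order accurate).
    """
    dt = window_ns / n_fine
    t = np.arange(n_fine) * dt
    center = irf.center_ns + shift_ns
    if irf.kind == "delta":
        kern = np.zeros(n_fine)
        kern[int(np.round((center % window_ns) / dt)) % n_fine] = 1.0
        return kern
    if irf.kind == "gaussian":
        sig = irf.sigma_ns
        kern = np.zeros(n_fine)
        for k in (-1, 0, 1):  # wrap the pulse across the period boundary
            kern += np.exp(-0.5 * ((t - center + k * window_ns) / sig) ** 2)
        s = kern.sum()
        if s <= 0:
            raise ConfigError("Gaussian IRF has no mass inside the window")
        return kern / s
    # measured
    h = irf.histogram
    if abs(h.window_ns - window_ns) > 1e-6 * window_ns:
        raise RegridRequiredError(
            f"measured IRF window {h.window_ns} ns incompatible with data "
            f"window {window_ns} ns; regrid the IRF first"
        )
    density = h.counts / np.maximum(h.bin_widths, 1e-300)
    kern = np.interp(
        (t - shift_ns) % window_ns, h.bin_centers, density, left=0.0, right=0.0
    )
    s = kern.sum()
    if s <= 0:
        raise DataError("measured IRF interpolates to zero everywhere")
    return kern / s


def _wrap_factor(tau: float, window_ns: float, wrap: bool) -> float:
    # sum over previous pulses: exp(-t/tau) + exp(-(t+T)/tau) + ...
    return 1.0 / (1.0 - np.exp(-window_ns / tau)) if wrap else 1.0


def _cell_averaged_density(components, window_ns, n_fine, wrap):
    """Decay rate averaged exactly over each fine cell.

    The exponential jumps at the excitation instant; exact per-cell
    integrals keep the discrete circular convolution second-order
    accurate there, where midpoint sampling would be first-order.
    """
    dt = window_ns / n_fine
    lefts = np.arange(n_fine) * dt
    dens = np.zeros(n_fine)
    for alpha, tau in components:
        w = _wrap_factor(tau, window_ns, wrap)
        dens += (
            alpha * w * tau / dt
            * (np.exp(-lefts / tau) - np.exp(-(lefts + dt) / tau))
        )
    return dens


def model_decay(
    model: DecayModel,
    irf: IRF,
    bin_edges: np.ndarray,
    oversample: int = 16,
    wrap: bool = True,
) -> np.ndarray:
    """Expected counts per bin for a model under reconvolution.

    With a delta IRF at zero offset the result equals the closed-form
    multi-exponential integrated over each bin; otherwise the model is
    circularly convolved with the IRF kernel on an oversampled grid
    (midpoint quadrature) and integrated per bin.
    """
    edges = _check_edges(bin_edges)
    window = float(edges[-1])
    offset = irf.center_ns + model.shift_ns

    if irf.kind == "delta" and abs(offset) < 1e-12:
        out = np.zeros(len(edges) - 1)
        for alpha, tau in model.components:
            w = _wrap_factor(tau, window, wrap)
            out += alpha * tau * w * (
                np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
            )
        return out + model.baseline

    widths = np.diff(edges)
    if not np.allclose(widths, widths[0], rtol=1e-9):
        raise ConfigError("reconvolution requires equal-width bins")
    if abs(edges[0]) > 1e-12:
        raise ConfigError("bin_edges must start at 0 for reconvolution")
    n_bins = len(edges) - 1
    n_fine = n_bins * oversample
    dt = window / n_fine

    dens = _cell_averaged_density(model.components, window, n_fine, wrap)
    kern = _irf_fine_kernel(irf, window, n_fine, model.shift_ns)
    conv = np.fft.irfft(np.fft.rfft(dens) * np.fft.rfft(kern), n=n_fine)
    expected = conv.reshape(n_bins, oversample).sum(axis=1) * dt
    return expected + model.baseline


# ---------------------------------------------------------------------------
# fitting


class _Forward:
    """Cached forward model: the IRF kernel FFT is computed once per fit."""

    def __init__(self, irf, edges, oversample, wrap):
        self.edges = edges
        self.window = float(edges[-1])
        self.wrap = wrap
        self.n_bins = len(edges) - 1
        self.oversample = oversample
        self.analytic = irf.kind == "delta" and abs(irf.center_ns) < 1e-12
        if not self.analytic:
            widths = np.diff(edges)
            if not np.allclose(widths, widths[0], rtol=1e-9):
                raise ConfigError("reconvolution requires equal-width bins")
            self.n_fine = self.n_bins * oversample
            self.dt = self.window / self.n_fine
            self.kern_fft = np.fft.rfft(
                _irf_fine_kernel(irf, self.window, self.n_fine, 0.0)
            )

    def __call__(self, taus, alphas, baseline):
        if self.analytic:
            e = self.edges
            out = np.zeros(self.n_bins)
            for a, tau in zip(alphas, taus):
                w = _wrap_factor(tau, self.window, self.wrap)
                out += a * tau * w * (np.exp(-e[:-1] / tau) - np.exp(-e[1:] / tau))
            return out + baseline
        dens = _cell_averaged_density(
            list(zip(alphas, taus)), self.window, self.n_fine, self.wrap
        )
        conv = np.fft.irfft(np.fft.rfft(dens) * self.kern_fft, n=self.n_fine)
        return conv.reshape(self.n_bins, self.oversample).sum(axis=1) * self.dt + baseline

    def basis(self, taus):
        """Unit-amplitude component curves, for the amplitude solve."""
        cols = [self(np.array([tau]), np.array([1.0]), 0.0) for tau in taus]
        return np.column_stack(cols)


def _poisson_nll(counts, expected):
    m = np.clip(expected, 1e-10, None)
    return float(np.sum(m - counts * np.log(m)))


def _wls(counts, expected):
    w = 1.0 / np.maximum(counts, 1.0)
    return float(np.sum(w * (counts - expected) ** 2))


def fit_decay(
    hist: DecayHistogram,
    irf: IRF,
    n_components: int = 1,
    objective: str = "poisson-mle",
    min_photons: int | None = DEFAULT_PHOTON_THRESHOLD,
    fit_baseline: bool = True,
    oversample: int = 16,
    wrap: bool = True,
    weighting: str = "amplitude",
) -> FitResult:
    """Fit a 1–3 component reconvolution model to a decay histogram.

    Raises :class:`InsufficientPhotonsError` below ``min_photons`` (pass
    ``None`` to disable the guard). When the optimizer stalls the best
    model found is returned with ``converged=False`` rather than raising.
    """
    if not 1 <= n_components <= 3:
        raise ConfigError("n_components must be 1, 2 or 3")
    if objective not in ("poisson-mle", "weighted-ls"):
        raise ConfigError(f"unknown objective {objective!r}")
    counts = np.asarray(hist.counts, dtype=float)
    if not np.all(np.isfinite(counts)):
        raise DataError("non-finite counts in decay histogram")
    total = float(counts.sum())
    if min_photons is not None and total < min_photons:
        raise InsufficientPhotonsError(
            f"{total:.0f} photons < threshold {min_photons}"
        )

    forward = _Forward(irf, _check_edges(hist.bin_edges), oversample, wrap)
    loss = _poisson_nll if objective == "poisson-mle" else _wls

    k = n_components
    grid = np.geomspace(0.1, 10.0, 5 if k > 1 else 6)
    tau_starts = list(itertools.combinations(grid, k))

    n_params = 2 * k + (1 if fit_baseline else 0)
    best = None
    for taus0 in tau_starts:
        taus0 = np.array(taus0)
        basis = forward.basis(taus0)
        cols = (
            np.column_stack([basis, np.ones(forward.n_bins)])
            if fit_baseline
            else basis
        )
        sol, _ = optimize.nnls(cols, counts)
        alphas0 = np.maximum(sol[:k], 1e-6 * max(total, 1.0))
        base0 = sol[k] if fit_baseline else 0.0

        x0 = np.concatenate(
            [np.log(taus0), np.log(alphas0), [base0] if fit_baseline else []]
        )
        lo = np.concatenate(
            [
                np.full(k, np.log(_TAU_BOUNDS[0])),
                np.full(k, -50.0),
                [0.0] if fit_baseline else [],
            ]
        )
        hi = np.concatenate(
            [
                np.full(k, np.log(_TAU_BOUNDS[1])),
                np.full(k, 50.0),
                [max(counts.max(), 1.0)] if fit_baseline else [],
            ]
        )

        def fun(x):
            taus = np.exp(x[:k])
            alphas = np.exp(x[k : 2 * k])
            base = x[2 * k] if fit_baseline else 0.0
            return loss(counts, forward(taus, alphas, base))

        res = optimize.minimize(
            fun,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        # ties: smaller objective wins; on near-ties prefer smaller tau_1
        if best is None or res.fun < best[0] - 1e-12:
            best = (res.fun, res)

    res = best[1]
    taus = np.exp(res.x[:k])
    alphas = np.exp(res.x[k : 2 * k])
    base = float(res.x[2 * k]) if fit_baseline else 0.0
    order = np.argsort(taus)
    model = DecayModel(
        components=[(float(alphas[i]), float(taus[i])) for i in order],
        baseline=base,
    )

    ident_flag = False
    if k >= 2:
        ts = np.sort(taus)
        if np.any(ts[1:] / ts[:-1] < _MIN_TAU_RATIO):
            ident_flag = True
            warnings.warn(
                f"fitted lifetimes {np.round(ts, 3)} closer than ratio "
                f"{_MIN_TAU_RATIO}: components not reliably separable",
                IdentifiabilityWarning,
                stacklevel=2,
            )

    expected = forward(taus, alphas, base)
    dof = max(forward.n_bins - n_params, 1)
    red_chi2 = float(
        np.sum((counts - expected) ** 2 / np.clip(expected, 1e-10, None)) / dof
    )
    return FitResult(
        model=model,
        tau_mean_ns=mean_lifetime(model, weighting),
        reduced_chi2=red_chi2,
        converged=bool(res.success),
        n_photons_used=int(round(total)),
        objective=objective,
        identifiability_flag=ident_flag,
    )


# ---------------------------------------------------------------------------
# whole-field fitting


@dataclass
class LifetimeImage:
    """Per-pixel lifetime map with companion count/convergence maps.

    Pixels below the photon threshold are NaN in ``tau_mean_ns`` and
    False in ``fitted`` — absent, not zero.
    """

    tau_mean_ns: np.ndarray
    counts: np.ndarray
    fitted: np.ndarray
    converged: np.ndarray
    fits: dict = field(default_factory=dict)


def fit_field(
    photons_by_pixel,
    irf: IRF,
    shape: tuple[int, int] | None = None,
    n_bins: int = 64,
    window_ns: float = 25.0,
    min_photons: int = DEFAULT_PHOTON_THRESHOLD,
    **fit_kwargs,
) -> LifetimeImage:
    """Fit every pixel of a field that meets the photon threshold.

    ``photons_by_pixel`` is either a mapping ``{(row, col): micro-times}``
    or a flat iterable of :class:`~flimcoloc.tcspc.PhotonRecord`. Pixels
    with no entry or too few photons are flagged absent.
    """
    if not isinstance(photons_by_pixel, dict):
        grouped: dict[tuple[int, int], list[float]] = {}
        for p in photons_by_pixel:
            if not isinstance(p, PhotonRecord):
                raise DataError("flat input must contain PhotonRecord objects")
            grouped.setdefault((p.y, p.x), []).append(p.t_ns)
        photons_by_pixel = grouped

    if shape is None:
        if photons_by_pixel:
            rows = max(y for y, _ in photons_by_pixel) + 1
            cols = max(x for _, x in photons_by_pixel) + 1
            shape = (rows, cols)
        else:
            shape = (0, 0)

    tau = np.full(shape, np.nan)
    cnt = np.zeros(shape, dtype=np.int64)
    fitted = np.zeros(shape, dtype=bool)
    conv = np.zeros(shape, dtype=bool)
    fits: dict[tuple[int, int], FitResult] = {}

    for (y, x), times in photons_by_pixel.items():
        times = np.asarray(times, dtype=float)
        cnt[y, x] = times.size
        if times.size < min_photons:
            continue
        hist = bin_photons(times, n_bins=n_bins, window_ns=window_ns)
        result = fit_decay(hist, irf, min_photons=min_photons, **fit_kwargs)
        tau[y, x] = result.tau_mean_ns
        fitted[y, x] = True
        conv[y, x] = result.converged
        fits[(y, x)] = result

    return LifetimeImage(tau, cnt, fitted, conv, fits)
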