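"""Seeded generators for synthetic TCSPC decays and nuclear images.

Two simulators stand in for the microscopy data:

* photon-counting decay simulation — arrival times drawn from the
  IRF-convolved multi-exponential density (exponential draw plus IRF
  jitter, wrapped at the repetition window), giving exactly the
  density the reconvolution model predicts;
* two-channel nuclear fields — disk nuclei containing DAPI-dense
  heterochromatin aggregates (~0.5-1.5 um disks) and DAPI-sparse
  euchromatic fine puncta (<0.3 um spots). Channel A carries the
  aggregate pattern; channel B is a rho-weighted mixture of channel A's
  pattern and an independent puncta pattern, so the ground-truth
  co-localization level is a single dial rho in [0, 1]. Gaussian PSF
  blur is applied before Poisson shot noise and Gaussian read noise
  (photon-limited imaging order).

Every generator is deterministic under its seed: identical specs
reproduce byte-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, PlacementError
from .lifetime import DecayModel, fit_decay
from .tcspc import DEFAULT_N_BINS, DEFAULT_WINDOW_NS, DecayHistogram, IRF, bin_photons


# ---------------------------------------------------------------------------
# decay simulation


@dataclass
class SyntheticDecaySpec:
    """Ground truth for a batch of simulated decay histograms."""

    model: DecayModel
    irf: IRF
    n_photons: int
    n_replicates: int = 1
    n_bins: int = DEFAULT_N_BINS
    window_ns: float = DEFAULT_WINDOW_NS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_photons <= 0:
            raise ConfigError("n_photons must be positive")
        if self.n_replicates <= 0:
            raise ConfigError("n_replicates must be positive")


def sample_arrival_times(
    model: DecayModel,
    irf: IRF,
    n_photons: int,
    window_ns: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw photon micro-times from the IRF-convolved decay density.

    Each photon picks a component with probability proportional to its
    photon share alpha_i * tau_i, draws an exponential waiting time,
    adds the IRF arrival jitter, and wraps modulo the repetition window
    (periodic re-excitation). The resulting wrapped density equals the
    circular convolution used by the reconvolution forward model.
    """
    alphas, taus = model.alphas, model.taus
    shares = alphas * taus
    if shares.sum() <= 0:
        raise ConfigError("decay model has no photon mass")
    probs = shares / shares.sum()
    comp = rng.choice(len(taus), size=n_photons, p=probs)
    t = rng.exponential(scale=taus[comp])
    center = irf.center_ns + model.shift_ns
    if irf.kind == "gaussian":
        t = t + rng.normal(center, irf.sigma_ns, size=n_photons)
    elif irf.kind == "delta":
        t = t + center
    else:  # measured: inverse-CDF draw from the IRF histogram
        h = irf.histogram
        cdf = np.cumsum(h.counts) / h.total_photons
        u = rng.random(n_photons)
        idx = np.searchsorted(cdf, u)
        frac = rng.random(n_photons)
        t = t + h.bin_edges[idx] + frac * h.bin_widths[idx]
    return np.mod(t, window_ns)


def simulate_decay(spec: SyntheticDecaySpec) -> list[DecayHistogram]:
    """Simulate ``n_replicates`` Poisson photon-counting decays."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_replicates):
        times = sample_arrival_times(
            spec.model, spec.irf, spec.n_photons, spec.window_ns, rng
        )
        out.append(bin_photons(times, n_bins=spec.n_bins, window_ns=spec.window_ns))
    return out


def simulate_fret_pair(
    tau_donor: float,
    tau_da: float,
    n_cells_each: int,
    fit_noise_sd: float = 0.05,
    seed: int = 0,
    mode: str = "fast",
    n_photons: int = 10_000,
    irf: IRF | None = None,
    n_bins: int = DEFAULT_N_BINS,
    window_ns: float = DEFAULT_WINDOW_NS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell lifetime samples for a donor-only and a donor+acceptor group.

    ``fast`` mode draws per-cell fitted lifetimes directly from
    Normal(tau, fit_noise_sd) truncated at zero — the distribution a
    well-behaved per-cell fit produces. ``full`` mode simulates one
    decay per cell at ``n_photons`` photons and runs the actual
    reconvolution fit. Returns (donor lifetimes, donor+acceptor
    lifetimes) in ns.
    """
    if tau_donor <= 0 or tau_da <= 0:
        raise ConfigError("lifetimes must be positive")
    if n_cells_each < 1:
        raise ConfigError("n_cells_each must be >= 1")
    if mode not in ("fast", "full"):
        raise ConfigError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "fast":
        donor = rng.normal(tau_donor, fit_noise_sd, size=n_cells_each)
        da = rng.normal(tau_da, fit_noise_sd, size=n_cells_each)
        return np.clip(donor, 1e-3, None), np.clip(da, 1e-3, None)

    irf = irf or IRF(kind="gaussian", center_ns=1.0, fwhm_ns=0.3)
    groups = []
    for tau in (tau_donor, tau_da):
        model = DecayModel(components=[(1.0, tau)])
        taus = []
        for _ in range(n_cells_each):
            times = sample_arrival_times(model, irf, n_photons, window_ns, rng)
            hist = bin_photons(times, n_bins=n_bins, window_ns=window_ns)
            taus.append(fit_decay(hist, irf, n_components=1).tau_mean_ns)
        groups.append(np.array(taus))
    return groups[0], groups[1]


# ---------------------------------------------------------------------------
# image simulation


@dataclass
class SyntheticFieldSpec:
    """Ground-truth parameters for one simulated two-channel field.

    Geometry defaults follow confocal imaging of brain-tissue nuclei at
    0.1 um/px: ~7 um nuclei, heterochromatin aggregates 0.5-1.5 um,
    euchromatic puncta below 0.3 um (1-3 px). ``mixing_rho`` is the
    ground-truth co-localization of channel B with channel A.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    n_nuclei: int = 4
    nucleus_diameter_um: float = 7.0
    nucleus_diameter_jitter_um: float = 0.5
    aggregate_diameter_range_um: tuple[float, float] = (0.5, 1.5)
    fine_puncta_diameter_um: float = 0.25
    n_aggregates_per_nucleus: int = 10
    n_puncta_per_nucleus: int = 120
    nucleoplasm_intensity: float = 0.1
    mixing_rho: float = 1.0
    psf_sigma_um: float = 0.1
    photon_budget_per_pixel: int | None = 200
    camera_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing_rho <= 1.0:
            raise ConfigError("mixing_rho must lie in [0, 1]")
        lo, hi = self.aggregate_diameter_range_um
        if not 0 < lo < hi:
            raise ConfigError("aggregate diameter range must satisfy 0 < low < high")
        for name in ("pixel_size_um", "nucleus_diameter_um", "psf_sigma_um",
                     "fine_puncta_diameter_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.photon_budget_per_pixel is not None and self.photon_budget_per_pixel <= 0:
            raise ConfigError("photon_budget_per_pixel must be positive or None")
        if self.camera_noise_sd < 0:
            raise ConfigError("camera_noise_sd must be non-negative")


def _disk_mask(shape, center, radius_px):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 < radius_px**2


def _place_nuclei(spec: SyntheticFieldSpec, rng) -> tuple[np.ndarray, list[dict]]:
    """Place non-overlapping disk nuclei; returns label mask + records."""
    shape = spec.image_shape
    labels = np.zeros(shape, dtype=np.int32)
    placed = []
    max_tries = 500
    for i in range(spec.n_nuclei):
        diam = spec.nucleus_diameter_um + rng.uniform(
            -spec.nucleus_diameter_jitter_um, spec.nucleus_diameter_jitter_um
        )
        r_px = 0.5 * diam / spec.pixel_size_um
        ok = False
        for _ in range(max_tries):
            cy = rng.uniform(r_px + 1, shape[0] - r_px - 1)
            cx = rng.uniform(r_px + 1, shape[1] - r_px - 1)
            if all(
                (cy - p["center"][0]) ** 2 + (cx - p["center"][1]) ** 2
                > (r_px + p["radius_px"] + 1) ** 2
                for p in placed
            ):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei} without "
                "overlap; lower n_nuclei or enlarge the field"
            )
        mask = _disk_mask(shape, (cy, cx), r_px)
        labels[mask] = i + 1
        placed.append(
            {"label": i + 1, "center": (cy, cx), "radius_px": r_px,
             "diameter_um": diam}
        )
    return labels, placed


def _scatter_disks(
    shape, nucleus, radii_px, rng, non_overlapping, margin_px=0.0, max_tries=200
):
    """Disk pattern inside one nucleus; returns a float image and centers."""
    img = np.zeros(shape)
    cy0, cx0 = nucleus["center"]
    R = nucleus["radius_px"]
    centers = []
    for r in radii_px:
        for _ in range(max_tries):
            ang = rng.uniform(0, 2 * np.pi)
            rad = (R - r) * np.sqrt(rng.random())
            if rad < 0:
                break
            cy, cx = cy0 + rad * np.sin(ang), cx0 + rad * np.cos(ang)
            if non_overlapping and any(
                (cy - py) ** 2 + (cx - px) ** 2 <= (r + pr + margin_px) ** 2
                for py, px, pr in centers
            ):
                continue
            img[_disk_mask(shape, (cy, cx), max(r, 0.71))] = 1.0
            centers.append((cy, cx, r))
            break
    return img, centers


def simulate_nucleus_field(spec: SyntheticFieldSpec):
    """Simulate one two-channel nuclear field.

    Returns ``(image, label_mask, truth)`` where ``image`` is a
    float array of shape (3, rows, cols) holding channel A (aggregate
    compartment), channel B (the rho-mixture), and a DAPI-like channel;
    ``label_mask`` labels nuclei 1..n (0 background); ``truth`` records
    the spec, the pre-blur compartment patterns, and per-nucleus
    geometry.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    labels, nuclei = _place_nuclei(spec, rng)

    aggregate_pattern = np.zeros(shape)
    puncta_pattern = np.zeros(shape)
    lo_um, hi_um = spec.aggregate_diameter_range_um
    aggregate_records = []
    for nuc in nuclei:
        diams_um = rng.uniform(lo_um, hi_um, size=spec.n_aggregates_per_nucleus)
        radii = 0.5 * diams_um / spec.pixel_size_um
        agg, centers = _scatter_disks(
            shape, nuc, radii, rng, non_overlapping=True, margin_px=2.0
        )
        aggregate_pattern += agg
        aggregate_records.append(
            {"label": nuc["label"], "requested_diameters_um": diams_um.tolist(),
             "n_placed": len(centers)}
        )
        r_punct = 0.5 * spec.fine_puncta_diameter_um / spec.pixel_size_um
        punct, _ = _scatter_disks(
            shape,
            nuc,
            np.full(spec.n_puncta_per_nucleus, r_punct),
            rng,
            non_overlapping=False,
        )
        puncta_pattern += punct

    nucleus_mask = labels > 0

    def _norm(p):
        m = p.max()
        return p / m if m > 0 else p

    base = spec.nucleoplasm_intensity * nucleus_mask
    channel_a = _norm(aggregate_pattern) + base
    channel_b = (
        spec.mixing_rho * _norm(aggregate_pattern)
        + (1.0 - spec.mixing_rho) * _norm(puncta_pattern)
        + base
    )
    dapi = _norm(aggregate_pattern) + 3.0 * base

    sigma_px = spec.psf_sigma_um / spec.pixel_size_um
    channels = [
        ndimage.gaussian_filter(c, sigma_px) for c in (channel_a, channel_b, dapi)
    ]

    if spec.photon_budget_per_pixel is not None:
        noisy = []
        for c in channels:
            scale = spec.photon_budget_per_pixel  # photons at unit intensity
            photons = rng.poisson(np.clip(c, 0, None) * scale).astype(float)
            if spec.camera_noise_sd > 0:
                photons += rng.normal(0, spec.camera_noise_sd, size=shape)
            noisy.append(photons)
        channels = noisy

    image = np.stack(channels).astype(np.float32)
    truth = {
        "mixing_rho": spec.mixing_rho,
        "seed": spec.seed,
        "nuclei": nuclei,
        "aggregates": aggregate_records,
        "aggregate_pattern": aggregate_pattern,
        "puncta_pattern": puncta_pattern,
        "nucleus_diameters_um": [n["diameter_um"] for n in nuclei],
    }
    return image, labels, truth
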