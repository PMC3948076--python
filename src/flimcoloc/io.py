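"""File I/O: TIFF image stacks, decay/photon CSV, results tables, config.

Formats touched: multi-channel TIFF (images, label masks, lifetime
maps), CSV (decay histograms: ``time_ns,counts`` with a ``# width_ns=``
comment; photon records: ``x,y,t_ns,channel``), TSV results with an
embedded provenance block, JSON fit results, YAML configuration.
Vendor TTTR binaries are out of scope: convert to the photon-record CSV
dialect upstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import ChannelError, ConfigError, DataError
from .tcspc import DecayHistogram, PhotonRecord


@dataclass
class RunConfig:
    """Flat pipeline configuration; CLI flags > config file > defaults."""

    pixel_size_um: float = 0.1
    window_ns: float = 25.0
    n_bins: int = 256
    photon_threshold: int = 500
    fret_significance_threshold: float = 0.05
    min_cells: int = 25
    coloc_reference_diameter_um: float | None = None
    tolerance: float = 0.10
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.photon_threshold <= 0 or self.min_cells <= 0:
            raise ConfigError("thresholds must be positive")
        if not 0 <= self.tolerance < 1:
            raise ConfigError("tolerance must lie in [0, 1)")
        if self.window_ns <= 0 or self.n_bins <= 0 or self.pixel_size_um <= 0:
            raise ConfigError("window_ns, n_bins, pixel_size_um must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def provenance_block(config: dict, seed: int) -> dict:
    """Provenance every output embeds: config hash, seed, tool version."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": int(seed),
        "tool_version": __version__,
    }


# ---------------------------------------------------------------------------
# images


def read_image_stack(path, channels=None) -> list[np.ndarray]:
    """Read a (multi-)channel TIFF as a list of 2-D grids.

    3-D stacks are interpreted channel-first (as written by
    :func:`write_image_stack`). ``channels`` selects indices; a missing
    index raises :class:`ChannelError` naming the available channels.
    """
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise DataError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")
    n = arr.shape[0]
    if channels is None:
        channels = range(n)
    out = []
    for c in channels:
        if not 0 <= c < n:
            raise ChannelError(
                f"channel {c} not in {path}; available: 0..{n - 1}"
            )
        out.append(arr[c])
    return out


def write_image_stack(path, image: np.ndarray) -> None:
    """Write a channel-first (C, rows, cols) stack as TIFF."""
    arr = np.asarray(image)
    kwargs = {"photometric": "minisblack"} if arr.ndim == 3 else {}
    tifffile.imwrite(path, arr, **kwargs)


def write_label_mask(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))


def read_label_mask(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)).astype(np.int32)


def write_lifetime_image(path, tau_map: np.ndarray) -> None:
    """32-bit float TIFF in ns; absent pixels are NaN."""
    tifffile.imwrite(path, np.asarray(tau_map, dtype=np.float32))


# ---------------------------------------------------------------------------
# decay / photon CSV


def write_decay_csv(path, hist: DecayHistogram) -> None:
    widths = hist.bin_widths
    with open(path, "w") as fh:
        fh.write(f"# width_ns={widths[0]:.9g}\n")
        fh.write("time_ns,counts\n")
        for left, c in zip(hist.bin_edges[:-1], hist.counts):
            fh.write(f"{left:.9g},{c:.9g}\n")


def read_decay_csv(path) -> DecayHistogram:
    width = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# width_ns="):
            width = float(first.split("=", 1)[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    if not {"time_ns", "counts"} <= set(df.columns):
        raise DataError(f"{path}: decay CSV needs columns time_ns,counts")
    lefts = df["time_ns"].to_numpy(dtype=float)
    if width is None:
        if len(lefts) < 2:
            raise DataError(f"{path}: cannot infer bin width")
        width = float(np.median(np.diff(lefts)))
    edges = np.append(lefts, lefts[-1] + width)
    # printed left edges carry decimal rounding: snap near-uniform grids
    # back to an exactly uniform one so reconvolution accepts them
    if len(lefts) >= 2:
        uniform = lefts[0] + width * np.arange(len(lefts) + 1)
        if np.allclose(edges, uniform, rtol=0, atol=1e-6 * width * len(lefts)):
            edges = uniform
    return DecayHistogram(edges, df["counts"].to_numpy())


def write_photon_csv(path, photons: list[PhotonRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("x,y,t_ns,channel\n")
        for p in photons:
            fh.write(f"{p.x},{p.y},{p.t_ns:.9g},{p.channel}\n")


def read_photon_csv(path) -> list[PhotonRecord]:
    df = pd.read_csv(path)
    needed = {"x", "y", "t_ns", "channel"}
    if not needed <= set(df.columns):
        raise DataError(f"{path}: photon CSV needs columns {sorted(needed)}")
    return [
        PhotonRecord(int(r.x), int(r.y), float(r.t_ns), str(r.channel))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# results


def write_results_tsv(path, table: pd.DataFrame, provenance: dict) -> None:
    """TSV with the provenance block as leading ``# key=value`` lines."""
    with open(path, "w") as fh:
        for k, v in provenance.items():
            fh.write(f"# {k}={v}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_results_tsv(path) -> tuple[pd.DataFrame, dict]:
    prov = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("# "):
            k, _, v = line[2:].strip().partition("=")
            prov[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, prov


def write_fit_json(path, fit, provenance: dict) -> None:
    payload = {
        "model": {
            "components": [[a, t] for a, t in fit.model.components],
            "baseline": fit.model.baseline,
            "shift_ns": fit.model.shift_ns,
        },
        "tau_mean_ns": fit.tau_mean_ns,
        "reduced_chi2": fit.reduced_chi2,
        "converged": fit.converged,
        "n_photons_used": fit.n_photons_used,
        "objective": fit.objective,
        "provenance": provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_json(path) -> dict:
    return json.loads(Path(path).read_text())
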