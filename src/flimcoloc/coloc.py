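"""Per-nucleus co-localization statistics for two-channel images.

Pearson's coefficient r measures intensity correlation over the pixels
of a nucleus (r = 1 complete positive correlation, -1 negative, 0
none). Manders' coefficients measure overlap fractions: M1 is the
fraction of channel-A intensity found in channel-B-positive pixels and
M2 the converse; both lie in [0, 1]. Nuclei are measured one ROI at a
time at one shared threshold setting, keeping only nuclei whose
equivalent diameter is within +/-10% of a reference diameter, and group
results are reported as mean +/- SEM over ~20 cells per staining.
Group differences use Student's t-test (two groups) or one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure

from .errors import (
    ConfigError,
    DataError,
    SampleSizeError,
    UndefinedCoefficientError,
    ZeroVarianceError,
)

DEFAULT_DIAMETER_TOLERANCE = 0.10


@dataclass
class NucleusROI:
    """One nucleus region of interest."""

    label: int
    mask: np.ndarray
    equivalent_diameter_um: float
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise DataError(f"empty mask for nucleus label {self.label}")


@dataclass
class ColocResult:
    """Per-nucleus coefficients plus the group summary (mean +/- SEM)."""

    per_nucleus: list[dict]
    group_mean_r: float
    group_sem_r: float | None
    n_cells: int


def pearson_coefficient(
    channel_a: np.ndarray, channel_b: np.ndarray, mask: np.ndarray
) -> float:
    """Product-moment correlation of two channels over masked pixels."""
    a = np.asarray(channel_a, float)[np.asarray(mask, bool)]
    b = np.asarray(channel_b, float)[np.asarray(mask, bool)]
    if a.size < 2:
        raise DataError("Pearson coefficient needs >= 2 masked pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroVarianceError(
            "a channel is constant within the mask; r is undefined"
        )
    r = float(np.corrcoef(a, b)[0, 1])
    if abs(r) > 1.0 - 1e-12:  # collapse sqrt rounding at the bounds
        r = float(np.sign(r))
    return r


def manders_coefficients(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    mask: np.ndarray,
    threshold_a: float = 0.0,
    threshold_b: float = 0.0,
) -> tuple[float, float]:
    """Manders' M1 and M2 over masked pixels.

    M1 = sum of channel-A intensity on pixels where B > threshold_b,
    divided by total channel-A intensity in the mask; M2 symmetric.
    Thresholds default to 0, i.e. any strictly positive partner
    intensity counts as co-occurring.
    """
    m = np.asarray(mask, bool)
    if not m.any():
        raise DataError("empty mask")
    a = np.asarray(channel_a, float)[m]
    b = np.asarray(channel_b, float)[m]
    tot_a, tot_b = a.sum(), b.sum()
    if tot_a <= 0 or tot_b <= 0:
        raise UndefinedCoefficientError(
            "zero total intensity in a channel; Manders undefined"
        )
    m1 = float(a[b > threshold_b].sum() / tot_a)
    m2 = float(b[a > threshold_a].sum() / tot_b)
    return m1, m2


def extract_rois(
    label_mask: np.ndarray, pixel_size_um: float
) -> list[NucleusROI]:
    """Nucleus ROIs from an integer label mask (0 = background)."""
    if pixel_size_um <= 0:
        raise ConfigError("pixel_size_um must be positive")
    label_mask = np.asarray(label_mask)
    rois = []
    for prop in measure.regionprops(label_mask):
        rois.append(
            NucleusROI(
                label=int(prop.label),
                mask=label_mask == prop.label,
                equivalent_diameter_um=float(
                    prop.equivalent_diameter_area * pixel_size_um
                ),
                centroid=tuple(prop.centroid),
            )
        )
    return rois


def select_nuclei(
    rois: list[NucleusROI],
    reference_diameter_um: float,
    tolerance: float = DEFAULT_DIAMETER_TOLERANCE,
) -> list[NucleusROI]:
    """Keep nuclei within +/-tolerance of the reference diameter.

    The interval [ref*(1-tol), ref*(1+tol)] is inclusive at both ends,
    so with tolerance 0 only exact matches survive.
    """
    if reference_diameter_um <= 0:
        raise ConfigError("reference_diameter_um must be positive")
    if not 0 <= tolerance < 1:
        raise ConfigError("tolerance must lie in [0, 1)")
    lo = reference_diameter_um * (1.0 - tolerance)
    hi = reference_diameter_um * (1.0 + tolerance)
    return [r for r in rois if lo <= r.equivalent_diameter_um <= hi]


def _modal_diameter(diameters: np.ndarray) -> float:
    """Reference diameter estimate: center of the densest histogram bin
    (median for very small samples, where a mode is not meaningful)."""
    diameters = np.asarray(diameters, float)
    if diameters.size < 4:
        return float(np.median(diameters))
    counts, edges = np.histogram(diameters, bins="auto")
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def analyze_field_coloc(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    label_mask: np.ndarray,
    pixel_size_um: float = 0.1,
    reference_diameter_um: float | None = None,
    tolerance: float = DEFAULT_DIAMETER_TOLERANCE,
    threshold_a: float = 0.0,
    threshold_b: float = 0.0,
) -> ColocResult:
    """Per-nucleus r/M1/M2 for one field, plus the group mean +/- SEM.

    All nuclei are measured at the same threshold settings. When no
    reference diameter is supplied it is estimated as the modal
    equivalent diameter of the segmented nuclei.
    """
    rois = extract_rois(label_mask, pixel_size_um)
    if not rois:
        raise DataError("label mask contains no nuclei")
    if reference_diameter_um is None:
        reference_diameter_um = _modal_diameter(
            [r.equivalent_diameter_um for r in rois]
        )
    kept = select_nuclei(rois, reference_diameter_um, tolerance)
    if not kept:
        raise DataError(
            "no nuclei within the diameter window "
            f"(reference {reference_diameter_um:.2f} um, +/-{tolerance:.0%})"
        )

    per_nucleus = []
    for roi in kept:
        r = pearson_coefficient(channel_a, channel_b, roi.mask)
        m1, m2 = manders_coefficients(
            channel_a, channel_b, roi.mask, threshold_a, threshold_b
        )
        per_nucleus.append(
            {
                "label": roi.label,
                "pearson_r": r,
                "manders_m1": m1,
                "manders_m2": m2,
                "equivalent_diameter_um": roi.equivalent_diameter_um,
            }
        )

    rs = np.array([p["pearson_r"] for p in per_nucleus])
    sem = float(stats.sem(rs)) if len(rs) >= 2 else None
    return ColocResult(
        per_nucleus=per_nucleus,
        group_mean_r=float(np.mean(rs)),
        group_sem_r=sem,
        n_cells=len(rs),
    )


def group_compare_coloc(groups: list) -> tuple[float, float]:
    """Compare per-nucleus coefficient samples across groups.

    Two groups: two-sided Student's t-test (equal variance). Three or
    more: one-way ANOVA. Returns (statistic, p_value). Exactly equal
    degenerate groups are handled as a zero statistic with p = 1.
    """
    if len(groups) < 2:
        raise ConfigError("need at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise SampleSizeError("each group needs >= 2 values")
    if all(np.var(g) == 0 for g in arrays):
        means = [np.mean(g) for g in arrays]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return float(t), float(p)
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
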