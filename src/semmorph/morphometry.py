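"""Object labeling, measurement, size-class grouping and summary statistics.

Segmented structures are labeled as 8-connected components, measured in
physical units (area from pixel count, diameter as the mean directional
Feret width, tube diameter from the distance transform along the medial
axis, wall thickness as the FWHM of an intensity ridge), grouped into
size classes by the exact 1-D least-squares partition, and summarized as
mean / SD (n-1) / SEM — the quantities reported for neuronal cell bodies
and axons in vitrified CNS tissue.

Conventions, stated for reproducibility: connectivity 8 for labeling;
boundary pixels are those with a 4-neighbour outside the object; Feret
widths are taken over 180 directions at 1 degree steps on boundary pixel
centers plus one pixel of extent; report rounding is half-away-from-zero
at the table's printed precision while internal values keep full
precision.
"""

from __future__ import annotations

import decimal
import importlib.resources
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.morphology import medial_axis

from .image import CalibratedImage
from .segmentation import FuzzyLabeling

__all__ = [
    "ObjectRecord",
    "GroupSummary",
    "WallMeasurement",
    "MissingObjectError",
    "label_objects",
    "measure_body",
    "measure_tube",
    "measure_wall_thickness",
    "classify_size_groups",
    "summarize_group",
    "round_half_away",
    "parse_measurement_table",
    "load_reference_cell_bodies",
    "load_reference_axon_diameters",
]


class MissingObjectError(KeyError):
    """Requested object id is absent from the label map."""


@dataclass
class ObjectRecord:
    """One segmented structure with its physical measurements."""

    object_id: int
    kind: str = "unknown"           # cell_body | axon_tube | unknown
    area_um2: float | None = None
    feret_diameter_um: float | None = None
    equiv_diameter_um: float | None = None
    tube_diameter_nm: float | None = None
    wall_thickness_nm: float | None = None
    centroid: tuple[float, float] | None = None
    n_pixels: int = 0
    n_boundary_pixels: int = 0
    group_label: str | None = None


@dataclass
class GroupSummary:
    """Per-size-class statistics (SEM here = standard error of the mean)."""

    group_label: str
    n: int
    mean_diameter_um: float
    sd_diameter_um: float | None
    sem_diameter_um: float | None
    mean_area_um2: float | None = None
    sd_area_um2: float | None = None
    sem_area_um2: float | None = None


@dataclass
class WallMeasurement:
    """FWHM wall-thickness result along a sampled profile."""

    detected: bool
    thickness_nm: float | None
    peak_position_px: float | None
    profile: np.ndarray = field(default_factory=lambda: np.empty(0))
    reason: str = ""


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------


def label_objects(
    labeling: FuzzyLabeling | np.ndarray,
    foreground_classes,
    min_area: int = 1,
    restrict_mask: np.ndarray | None = None,
) -> tuple[list[ObjectRecord], np.ndarray, int]:
    """8-connected components of the selected classes.

    Accepts a :class:`FuzzyLabeling` (uses its hard labels) or a raw
    integer label field. Components smaller than ``min_area`` pixels are
    discarded and counted; surviving labels are dense from 1. Returns
    (record stubs, label map, n_rejected).
    """
    hard = labeling.hard_labels if isinstance(labeling, FuzzyLabeling) else labeling
    fg = np.isin(hard, list(foreground_classes))
    if restrict_mask is not None:
        fg &= restrict_mask
    lbl = skmeasure.label(fg, connectivity=2)
    out = np.zeros_like(lbl)
    records: list[ObjectRecord] = []
    rejected = 0
    next_id = 1
    for region_id in range(1, lbl.max() + 1):
        mask = lbl == region_id
        n = int(mask.sum())
        if n < min_area:
            rejected += 1
            continue
        out[mask] = next_id
        records.append(ObjectRecord(object_id=next_id, n_pixels=n))
        next_id += 1
    return records, out, rejected


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    # boundary = object pixels with a 4-neighbour outside the object
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


def _feret_mean(mask: np.ndarray, n_directions: int = 180) -> float:
    """Mean directional Feret width in pixels (pixel extent included)."""
    boundary = np.argwhere(_boundary_pixels(mask)).astype(float)
    angles = np.deg2rad(np.arange(n_directions))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (D, 2)
    proj = boundary @ dirs.T  # (Npix, D)
    widths = proj.max(axis=0) - proj.min(axis=0) + 1.0
    return float(widths.mean())


def measure_body(label_map: np.ndarray, object_id: int,
                 pixel_size: float) -> ObjectRecord:
    """Area, mean Feret and equivalent-circle diameter of one object.

    Area is pixel count x pixel area (um^2); diameters are in um.
    Diameter and area are measured independently (Feret vs pixel count) —
    the reported tables list both and they are not circular equivalents of
    one another.
    """
    mask = label_map == object_id
    if not mask.any():
        raise MissingObjectError(f"object id {object_id} not in label map")
    n = int(mask.sum())
    area_um2 = n * (pixel_size / 1000.0) ** 2
    feret_um = _feret_mean(mask) * pixel_size / 1000.0
    equiv_um = 2.0 * np.sqrt(area_um2 / np.pi)
    cy, cx = ndimage.center_of_mass(mask)
    return ObjectRecord(
        object_id=int(object_id),
        kind="cell_body",
        area_um2=area_um2,
        feret_diameter_um=feret_um,
        equiv_diameter_um=float(equiv_um),
        centroid=(float(cy), float(cx)),
        n_pixels=n,
        n_boundary_pixels=int(_boundary_pixels(mask).sum()),
    )


def _skeleton_endpoints(skel: np.ndarray) -> np.ndarray:
    neighbours = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3)),
                                  mode="constant") - 1
    return skel & (neighbours <= 1)


def measure_tube(mask: np.ndarray, pixel_size: float):
    """Tube diameter as twice the mean medial-axis distance, in nm.

    Skeleton points within one mean width of a skeleton endpoint are
    excluded so the rounded tips do not bias the width. Returns
    (diameter_nm, local width profile in nm, kind) where kind is
    ``axon_tube`` when the skeleton is at least twice as long as the mean
    width (the elongation rule) and ``unknown`` otherwise.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    skel, dist = medial_axis(mask, return_distance=True)
    pts = np.argwhere(skel)
    if len(pts) == 0:  # degenerate single-pixel object
        widths_px = np.array([2.0 * dist[mask].max()])
        return float(widths_px[0] * pixel_size), widths_px * pixel_size, "unknown"
    widths_px = 2.0 * dist[skel]
    mean_width = float(widths_px.mean())
    endpoints = np.argwhere(_skeleton_endpoints(skel))
    keep = np.ones(len(pts), dtype=bool)
    if len(endpoints):
        d2ep = np.min(
            ((pts[:, None, :] - endpoints[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        keep = d2ep > mean_width**2
        if not keep.any():
            keep[:] = True  # tube shorter than its width: keep everything
    kept_widths = 2.0 * dist[tuple(pts[keep].T)]
    diameter_nm = float(kept_widths.mean() * pixel_size)
    kind = "axon_tube" if len(pts) >= 2.0 * mean_width else "unknown"
    return diameter_nm, kept_widths * pixel_size, kind


def measure_wall_thickness(
    image: CalibratedImage,
    crossing_segment,
    pixel_size: float | None = None,
    step_px: float = 0.25,
    noise_floor: float | None = None,
) -> WallMeasurement:
    """FWHM of the intensity ridge crossed by a segment, in nm.

    The profile is sampled at ``step_px`` (default 0.25 pixel) steps with
    bilinear interpolation; a linear baseline between the two profile ends
    is subtracted; the ridge peak must exceed the noise floor (default
    4x a robust first-difference noise estimate) or a ``no-wall-detected``
    result is returned. Half-maximum crossings are located by linear
    interpolation on each side of the peak.
    """
    pixel_size = pixel_size or image.pixel_size
    (r0, c0), (r1, c1) = crossing_segment
    length_px = float(np.hypot(r1 - r0, c1 - c0))
    if length_px <= 0:
        raise ValueError("degenerate crossing segment")
    n = max(int(np.ceil(length_px / step_px)) + 1, 5)
    t = np.linspace(0.0, 1.0, n)
    rows = r0 + t * (r1 - r0)
    cols = c0 + t * (c1 - c0)
    vals = ndimage.map_coordinates(image.pixels, [rows, cols], order=1,
                                   mode="nearest")
    step_actual = length_px / (n - 1)

    edge = max(2, n // 20)
    left_base = float(vals[:edge].mean())
    right_base = float(vals[-edge:].mean())
    baseline = left_base + (right_base - left_base) * t
    ridge = vals - baseline

    diffs = np.abs(np.diff(ridge))
    sigma = 1.4826 * float(np.median(diffs)) / np.sqrt(2.0)
    floor = noise_floor if noise_floor is not None else max(4.0 * sigma, 1e-3)

    ipk = int(np.argmax(ridge))
    peak = float(ridge[ipk])
    if peak < floor:
        return WallMeasurement(False, None, None, vals, reason="no-wall-detected")
    half = peak / 2.0

    def _cross(idx_range):
        prev = ipk
        for i in idx_range:
            if ridge[i] < half:
                # linear interpolation between i and prev
                frac = (half - ridge[i]) / (ridge[prev] - ridge[i])
                return i + frac * (prev - i)
            prev = i
        return float(idx_range[-1]) if len(idx_range) else float(ipk)

    left = _cross(range(ipk - 1, -1, -1))
    right = _cross(range(ipk + 1, n))
    thickness_nm = (right - left) * step_actual * pixel_size
    return WallMeasurement(True, float(thickness_nm), float(ipk * step_actual),
                           vals)


# ---------------------------------------------------------------------------
# Grouping and statistics
# ---------------------------------------------------------------------------


def _optimal_1d_partition(sorted_vals: np.ndarray, k: int):
    """Exact least-squares partition of sorted values into k contiguous
    groups, by dynamic programming over prefix sums (no random init)."""
    n = len(sorted_vals)
    s1 = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    s2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def cost(a: int, b: int) -> float:  # values a..b-1
        m = b - a
        tot = s1[b] - s1[a]
        return float(s2[b] - s2[a] - tot * tot / m)

    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for j in range(1, k + 1):
        for i in range(j, n + 1):
            best, best_a = INF, j - 1
            for a in range(j - 1, i):
                c = dp[j - 1, a] + cost(a, i)
                if c < best:
                    best, best_a = c, a
            dp[j, i] = best
            cut[j, i] = best_a
    bounds = [n]
    i = n
    for j in range(k, 0, -1):
        i = cut[j, i]
        bounds.append(i)
    return bounds[::-1]  # k+1 ascending cut positions, 0 ... n


def classify_size_groups(diameters, k: int = 3,
                         labels: list[str] | None = None) -> np.ndarray:
    """Exact 1-D least-squares k-partition of diameters into size classes.

    Groups are labeled 1A, 1B, ... by *descending* mean diameter (1A is
    the largest class). Returns one label per input value, in input order.
    """
    vals = np.asarray(diameters, dtype=float)
    if vals.ndim != 1:
        raise ValueError("diameters must be 1-D")
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(vals) < k:
        raise ValueError(f"need at least k={k} values, got {len(vals)}")
    order = np.argsort(vals, kind="stable")
    bounds = _optimal_1d_partition(vals[order], k)
    group_of_sorted = np.empty(len(vals), dtype=int)
    means = []
    for g in range(k):
        sl = slice(bounds[g], bounds[g + 1])
        group_of_sorted[sl] = g
        means.append(vals[order][sl].mean())
    # rank groups by descending mean: largest -> label index 0 ('1A')
    rank = {g: r for r, g in enumerate(np.argsort(means)[::-1])}
    if labels is None:
        labels = [f"1{chr(ord('A') + r)}" for r in range(k)]
    out = np.empty(len(vals), dtype=object)
    out[order] = [labels[rank[g]] for g in group_of_sorted]
    return out


def summarize_group(values) -> tuple[float, float | None, float | None]:
    """(mean, SD, SEM) with an n-1 denominator; SD/SEM absent for n=1."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one value")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, None, None
    sd = float(vals.std(ddof=1))
    return mean, sd, sd / np.sqrt(vals.size)


def round_half_away(x: float, ndigits: int) -> float:
    """Half-away-from-zero rounding at the table's printed precision."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------


def parse_measurement_table(source, sep: str = ";", decimal: str = ",") -> pd.DataFrame:
    """Read a measurement table that may use comma decimal separators."""
    if isinstance(source, str) and "\n" in source:
        source = StringIO(source)
    return pd.read_csv(source, sep=sep, decimal=decimal)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("semmorph") / "data" / name)


def load_reference_cell_bodies() -> pd.DataFrame:
    """Bundled spinal-cord cell-body table: group, diameter (um), area (um^2)."""
    return parse_measurement_table(_data_path("cell_bodies_spinal.csv"))


def load_reference_axon_diameters() -> pd.DataFrame:
    """Bundled axon-diameter table (nm) for brain and spinal cord."""
    return parse_measurement_table(_data_path("axon_diameters.csv"))
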