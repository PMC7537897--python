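"""Synthetic SEM-like scenes of neuronal ultrastructure with ground truth.

Renders the structures seen in vitrified CNS tissue — axon-like tubes,
round cell bodies with membranes and filamentous interiors, concentric
multilamellar (compact-myelin) rings — onto a calibrated grid, applies a
simple detector-noise chain, and records per-primitive truth masks and
parameters so every downstream measurement stage can be validated without
real micrographs.

Rasterization convention: pixel-center sampling on a 0-based (row, col)
grid; a pixel belongs to a primitive iff its center lies inside the
analytic boundary. Images are rendered as float intensities in [0, 1];
quantization to 8/16-bit happens only at file write.

Determinism: the noiseless render depends only on the primitives (textured
primitives carry their own ``texture_seed``); the scene ``seed`` drives
only the noise chain, so identical inputs give byte-identical images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import CalibratedImage

__all__ = [
    "Tube",
    "Body",
    "LamellarRing",
    "FilamentTexture",
    "NoiseModel",
    "TruthRecord",
    "GroundTruth",
    "PrimitiveOutOfBoundsError",
    "generate_scene",
    "sample_axon_population",
    "write_scene",
    "scene_from_config",
]

DEFAULT_BACKGROUND = 0.2


class PrimitiveOutOfBoundsError(ValueError):
    """A primitive lies fully outside the declared image bounds."""


# ---------------------------------------------------------------------------
# Scene primitives. All lengths are physical (nm); positions are pixel
# coordinates (row, col) so scenes can be laid out directly on the grid.
# ---------------------------------------------------------------------------


@dataclass
class Tube:
    """Axon-like tubular structure along a polyline centerline.

    ``lumen_diameter_nm`` is the inner (lumen) diameter and
    ``wall_thickness_nm`` the thickness of the bright wall on each side;
    the outer diameter is lumen + 2*wall. ``contrast`` is the signed wall
    intensity offset from background; the lumen sits at background +
    ``lumen_contrast``.
    """

    centerline: np.ndarray  # (M, 2) pixel coords, row/col
    lumen_diameter_nm: float
    wall_thickness_nm: float
    contrast: float = 0.5
    lumen_contrast: float = 0.0

    kind = "tube"

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[1] != 2:
            raise ValueError("centerline must be (M, 2) row/col coordinates")
        if not (self.lumen_diameter_nm > 0 and self.wall_thickness_nm > 0):
            raise ValueError("tube lengths must be > 0")

    def outer_diameter_nm(self) -> float:
        return self.lumen_diameter_nm + 2 * self.wall_thickness_nm


@dataclass
class Body:
    """Round cell body: disc interior, optional membrane rim and filaments."""

    center: tuple[float, float]  # (row, col) pixels
    outer_diameter_nm: float
    membrane_thickness_nm: float = 0.0
    filament_density: float = 0.0  # in [0, 1]
    contrast: float = 0.5
    membrane_contrast: float | None = None  # defaults to 1.2 * contrast
    texture_seed: int = 0

    kind = "body"

    def __post_init__(self) -> None:
        if not self.outer_diameter_nm > 0:
            raise ValueError("outer_diameter_nm must be > 0")
        if not 0.0 <= self.filament_density <= 1.0:
            raise ValueError("filament_density must lie in [0, 1]")
        if self.membrane_thickness_nm < 0:
            raise ValueError("membrane_thickness_nm must be >= 0")


@dataclass
class LamellarRing:
    """Concentric multilamellar rings (compact-myelin stand-in).

    ``n_layers`` bright bands of width period/2 start at ``inner_radius_nm``
    with radial spacing ``period_nm``; alternating bands are attenuated by
    ``amplitude_ratio`` (major dense vs intraperiod lines).
    """

    center: tuple[float, float]
    inner_radius_nm: float
    n_layers: int
    period_nm: float
    amplitude_ratio: float = 1.0  # in (0, 1]
    contrast: float = 0.5

    kind = "lamellar_ring"

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not (0.0 < self.amplitude_ratio <= 1.0):
            raise ValueError("amplitude_ratio must lie in (0, 1]")
        if not (self.inner_radius_nm > 0 and self.period_nm > 0):
            raise ValueError("lengths must be > 0")

    def outer_radius_nm(self) -> float:
        return self.inner_radius_nm + self.n_layers * self.period_nm


@dataclass
class FilamentTexture:
    """Disc-shaped patch of band-passed texture (filaments / nanovesicles)."""

    center: tuple[float, float]
    diameter_nm: float
    density: float = 0.5
    contrast: float = 0.2
    texture_seed: int = 0

    kind = "filament_texture"

    def __post_init__(self) -> None:
        if not self.diameter_nm > 0:
            raise ValueError("diameter_nm must be > 0")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")


@dataclass
class NoiseModel:
    """Detector-noise chain: blur -> Poisson -> Gaussian -> gradient.

    ``blur_fwhm_nm`` stands in for the beam point spread;
    ``poisson_scale`` is the expected count per unit intensity (0 disables);
    ``background_gradient`` is a low-order polynomial coefficient matrix
    c[i, j] multiplying (row/H)^i (col/W)^j, added last. With every
    parameter zero the rendered image equals the noiseless rasterization
    exactly.
    """

    gaussian_sigma: float = 0.0
    poisson_scale: float = 0.0
    background_gradient: np.ndarray | None = None
    blur_fwhm_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.poisson_scale < 0 or self.blur_fwhm_nm < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.background_gradient is not None:
            self.background_gradient = np.atleast_2d(
                np.asarray(self.background_gradient, dtype=float)
            )

    def is_zero(self) -> bool:
        grad = self.background_gradient
        return (
            self.gaussian_sigma == 0
            and self.poisson_scale == 0
            and self.blur_fwhm_nm == 0
            and (grad is None or not np.any(grad))
        )


@dataclass
class TruthRecord:
    """Ground truth for one rendered primitive."""

    index: int
    kind: str
    mask: np.ndarray  # bool, image shape
    params: dict
    truncated: bool = False
    overlaps: bool = False
    wall_mask: np.ndarray | None = None  # tubes only: the wall annulus


@dataclass
class GroundTruth:
    """All accepted primitives of a scene plus a composite label map."""

    records: list[TruthRecord] = field(default_factory=list)
    label_map: np.ndarray | None = None  # int, 0 = background, i+1 = record i

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _pixel_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    return rows, cols


def _distance_to_polyline(rows, cols, pts: np.ndarray) -> np.ndarray:
    """Min Euclidean distance (px) from each pixel center to the polyline."""
    rr = np.broadcast_to(rows, (rows.shape[0], cols.shape[1])).ravel()
    cc = np.broadcast_to(cols, (rows.shape[0], cols.shape[1])).ravel()
    p = np.stack([rr, cc], axis=1)
    if len(pts) == 1:
        return np.linalg.norm(p - pts[0], axis=1).reshape(rows.shape[0], cols.shape[1])
    best = np.full(p.shape[0], np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.linalg.norm(p - a, axis=1)
        else:
            t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(p - proj, axis=1)
        np.minimum(best, d, out=best)
    return best.reshape(rows.shape[0], cols.shape[1])


def _smooth_texture(shape, sigma_px, rng) -> np.ndarray:
    """Zero-mean unit-std band-limited noise field."""
    t = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    sd = t.std()
    return t / sd if sd > 0 else t


def _render_tube(prim: Tube, shape, pixel_size, background):
    rows, cols = _pixel_grid(shape)
    d_px = _distance_to_polyline(rows, cols, prim.centerline)
    lumen_r = prim.lumen_diameter_nm / 2 / pixel_size
    outer_r = lumen_r + prim.wall_thickness_nm / pixel_size
    mask = d_px <= outer_r
    lumen = d_px <= lumen_r
    wall = mask & ~lumen
    intensity = np.where(wall, background + prim.contrast,
                         background + prim.lumen_contrast)
    params = {
        "diameter_nm": prim.outer_diameter_nm(),
        "lumen_diameter_nm": prim.lumen_diameter_nm,
        "wall_nm": prim.wall_thickness_nm,
    }
    in_bounds = _polyline_in_bounds(prim, shape, pixel_size)
    return mask, intensity, params, wall, in_bounds


def _polyline_in_bounds(prim: Tube, shape, pixel_size) -> bool:
    outer_r = (prim.lumen_diameter_nm / 2 + prim.wall_thickness_nm) / pixel_size
    r = prim.centerline[:, 0]
    c = prim.centerline[:, 1]
    return bool(
        (r - outer_r >= 0).all()
        and (r + outer_r <= shape[0] - 1).all()
        and (c - outer_r >= 0).all()
        and (c + outer_r <= shape[1] - 1).all()
    )


def _render_body(prim: Body, shape, pixel_size, background):
    rows, cols = _pixel_grid(shape)
    d_px = np.hypot(rows - prim.center[0], cols - prim.center[1])
    r_out = prim.outer_diameter_nm / 2 / pixel_size
    mask = d_px <= r_out
    intensity = np.full(shape, background + prim.contrast)
    if prim.membrane_thickness_nm > 0:
        mc = prim.membrane_contrast
        if mc is None:
            mc = min(1.2 * prim.contrast, 1.0 - background)
        rim = mask & (d_px > r_out - prim.membrane_thickness_nm / pixel_size)
        intensity[rim] = background + mc
    if prim.filament_density > 0:
        rng = np.random.default_rng(prim.texture_seed)
        tex = _smooth_texture(shape, 2.0, rng)
        interior = mask & (d_px <= r_out - prim.membrane_thickness_nm / pixel_size)
        intensity = np.where(
            interior,
            intensity + 0.3 * prim.filament_density * prim.contrast * tex,
            intensity,
        )
    params = {"diameter_nm": prim.outer_diameter_nm,
              "membrane_nm": prim.membrane_thickness_nm}
    in_bounds = (
        prim.center[0] - r_out >= 0
        and prim.center[0] + r_out <= shape[0] - 1
        and prim.center[1] - r_out >= 0
        and prim.center[1] + r_out <= shape[1] - 1
    )
    return mask, intensity, params, None, in_bounds


def _render_ring(prim: LamellarRing, shape, pixel_size, background):
    rows, cols = _pixel_grid(shape)
    d_nm = np.hypot(rows - prim.center[0], cols - prim.center[1]) * pixel_size
    r0, p, L = prim.inner_radius_nm, prim.period_nm, prim.n_layers
    mask = (d_nm >= r0) & (d_nm <= r0 + L * p)
    phase = (d_nm - r0) / p
    layer = np.floor(phase).astype(int)
    in_band = mask & ((phase - layer) < 0.5) & (layer < L)
    amp = np.where(layer % 2 == 0, prim.contrast, prim.contrast * prim.amplitude_ratio)
    intensity = np.where(in_band, background + amp, background)
    peak_radii = [r0 + (k + 0.25) * p for k in range(L)]
    params = {
        "inner_radius_nm": r0,
        "period_nm": p,
        "n_layers": L,
        "peak_radii_nm": peak_radii,
        "diameter_nm": 2 * prim.outer_radius_nm(),
    }
    r_out = prim.outer_radius_nm() / pixel_size
    in_bounds = (
        prim.center[0] - r_out >= 0
        and prim.center[0] + r_out <= shape[0] - 1
        and prim.center[1] - r_out >= 0
        and prim.center[1] + r_out <= shape[1] - 1
    )
    return mask, intensity, params, None, in_bounds


def _render_texture(prim: FilamentTexture, shape, pixel_size, background):
    rows, cols = _pixel_grid(shape)
    d_px = np.hypot(rows - prim.center[0], cols - prim.center[1])
    r = prim.diameter_nm / 2 / pixel_size
    mask = d_px <= r
    rng = np.random.default_rng(prim.texture_seed)
    tex = _smooth_texture(shape, 1.5, rng)
    intensity = background + prim.contrast * prim.density * tex
    params = {"diameter_nm": prim.diameter_nm, "density": prim.density}
    in_bounds = (
        prim.center[0] - r >= 0
        and prim.center[0] + r <= shape[0] - 1
        and prim.center[1] - r >= 0
        and prim.center[1] + r <= shape[1] - 1
    )
    return mask, intensity, params, None, in_bounds


_RENDERERS = {
    "tube": _render_tube,
    "body": _render_body,
    "lamellar_ring": _render_ring,
    "filament_texture": _render_texture,
}


def generate_scene(
    primitives,
    noise: NoiseModel,
    shape: tuple[int, int],
    pixel_size: float,
    seed: int = 0,
    background: float = DEFAULT_BACKGROUND,
) -> tuple[CalibratedImage, GroundTruth]:
    """Rasterize primitives, apply the noise chain, return image + truth.

    Overlapping primitives are composited later-over-earlier and both get
    their ``overlaps`` flag set; a primitive fully outside the bounds
    raises :class:`PrimitiveOutOfBoundsError`; one that merely extends past
    the border is rendered clipped and flagged ``truncated``.
    """
    shape = (int(shape[0]), int(shape[1]))
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("shape must be positive")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")

    img = np.full(shape, float(background))
    truth = GroundTruth(label_map=np.zeros(shape, dtype=np.int32))
    occupied = np.zeros(shape, dtype=bool)

    for idx, prim in enumerate(primitives):
        renderer = _RENDERERS.get(prim.kind)
        if renderer is None:
            raise ValueError(f"unknown primitive kind {prim.kind!r}")
        mask, intensity, params, wall_mask, in_bounds = renderer(
            prim, shape, pixel_size, background
        )
        if not mask.any():
            raise PrimitiveOutOfBoundsError(
                f"primitive {idx} ({prim.kind}) lies fully outside the image"
            )
        overlaps = bool((mask & occupied).any())
        if overlaps:
            for rec in truth.records:
                if (rec.mask & mask).any():
                    rec.overlaps = True
        img = np.where(mask, intensity, img)  # later over earlier
        area_nm2 = float(mask.sum()) * pixel_size**2
        params = dict(params)
        params["area_nm2"] = area_nm2
        rec = TruthRecord(
            index=idx,
            kind=prim.kind,
            mask=mask,
            params=params,
            truncated=not in_bounds,
            overlaps=overlaps,
            wall_mask=wall_mask,
        )
        truth.records.append(rec)
        truth.label_map[mask] = idx + 1
        occupied |= mask

    img = np.clip(img, 0.0, 1.0)
    img = _apply_noise(img, noise, pixel_size, seed)
    return (
        CalibratedImage(img, pixel_size, source_id=f"synthetic:seed={seed}"),
        truth,
    )


def _apply_noise(img: np.ndarray, noise: NoiseModel, pixel_size: float,
                 seed: int) -> np.ndarray:
    if noise.is_zero():
        return img
    rng = np.random.default_rng(seed)
    out = img
    if noise.blur_fwhm_nm > 0:
        sigma_px = noise.blur_fwhm_nm / (2.3548 * pixel_size)
        out = ndimage.gaussian_filter(out, sigma_px)
    if noise.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.poisson_scale)
        out = out / noise.poisson_scale
    if noise.gaussian_sigma > 0:
        out = out + rng.normal(0.0, noise.gaussian_sigma, out.shape)
    grad = noise.background_gradient
    if grad is not None and np.any(grad):
        h, w = out.shape
        y = np.arange(h)[:, None] / max(h - 1, 1)
        x = np.arange(w)[None, :] / max(w - 1, 1)
        field = np.zeros_like(out)
        for i in range(grad.shape[0]):
            for j in range(grad.shape[1]):
                if grad[i, j]:
                    field += grad[i, j] * y**i * x**j
        out = out + field
    return np.clip(out, 0.0, 1.0)


def sample_axon_population(
    n: int,
    mean_diameter: float,
    sd: float,
    seed: int = 0,
    floor: float = 50.0,
) -> np.ndarray:
    """Draw ``n`` axon diameters (nm) from a normal truncated at ``floor``.

    The defaults model white-matter axons in the 0.5-0.8 um range; the
    50 nm floor keeps every draw physically positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not mean_diameter > 0:
        raise ValueError("mean_diameter must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if not floor > 0:
        raise ValueError("floor must be > 0")
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean_diameter, sd, size=int(n))
    return np.maximum(draws, floor)


# ---------------------------------------------------------------------------
# File interchange
# ---------------------------------------------------------------------------


def write_scene(outdir, image: CalibratedImage, truth: GroundTruth,
                stem: str = "scene") -> dict:
    """Write the image (16-bit TIFF), label TIFF and a JSON truth sidecar."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img_path = outdir / f"{stem}.tif"
    lbl_path = outdir / f"{stem}_labels.tif"
    json_path = outdir / f"{stem}_truth.json"
    tifffile.imwrite(img_path, np.round(image.pixels * 65535).astype(np.uint16))
    tifffile.imwrite(lbl_path, truth.label_map.astype(np.int32))
    sidecar = {
        "pixel_size_nm": image.pixel_size,
        "records": [
            {
                "index": r.index,
                "kind": r.kind,
                "truncated": r.truncated,
                "overlaps": r.overlaps,
                "params": r.params,
            }
            for r in truth.records
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return {"image": str(img_path), "labels": str(lbl_path), "truth": str(json_path)}


def scene_from_config(cfg: dict):
    """Build (primitives, noise, shape, pixel_size, seed) from a dict/YAML."""
    kinds = {
        "tube": Tube,
        "body": Body,
        "lamellar_ring": LamellarRing,
        "filament_texture": FilamentTexture,
    }
    prims = []
    for spec in cfg.get("primitives", []):
        spec = dict(spec)
        kind = spec.pop("kind")
        cls = kinds.get(kind)
        if cls is None:
            raise ValueError(f"unknown primitive kind {kind!r}")
        if kind in ("body", "lamellar_ring", "filament_texture"):
            spec["center"] = tuple(spec["center"])
        prims.append(cls(**spec))
    noise = NoiseModel(**cfg.get("noise", {}))
    shape = tuple(cfg["shape"])
    pixel_size = float(cfg["pixel_size_nm"])
    seed = int(cfg.get("seed", 0))
    background = float(cfg.get("background", DEFAULT_BACKGROUND))
    return prims, noise, shape, pixel_size, seed, background
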