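"""Seeded dermoscopy-like fixtures: lesion masks and rendered images.

Masks are star-convex blobs — a radial profile ``r(theta) = r0 * (1 +
roughness * smooth_noise(theta))`` around a random centre, rasterised and
filled — which guarantees a single 4-connected lesion region with an
irregular border.  Images are a skin-toned background with spatially
correlated noise, a darkened lesion with a smooth intensity falloff at
the border (blurred-edge look), and optional hair strokes and a dark
corner vignette mimicking common dermoscopy artefacts.

Everything is driven by a single RNG seed: the same config always yields
byte-identical image/mask pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError

__all__ = ["SynthConfig", "generate_lesion_mask", "render_image",
           "generate_pair", "generate_dataset"]

_SKIN_RGB = np.array([218.0, 170.0, 140.0])  # light skin tone, 8-bit scale
_NOISE_STD = 6.0     # background texture amplitude (8-bit units)
_LESION_DARKEN = 0.8  # fraction of 255 removed at contrast=1
_EDGE_FALLOFF_PX = 5.0  # width of the blurred lesion edge


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic dermoscopy fixture.

    ``lesion_area_range`` is a (min, max) fraction of the image area;
    ``boundary_roughness`` is the radial perturbation amplitude as a
    fraction of the mean radius; ``contrast`` in [0, 1] scales the
    lesion-vs-skin intensity gap; ``texture_scale`` is the correlation
    length (pixels) of the background noise.
    """

    height: int = 375
    width: int = 500
    lesion_area_range: tuple[float, float] = (0.1, 0.4)
    boundary_roughness: float = 0.3
    contrast: float = 0.5
    texture_scale: float = 8.0
    hair: bool = False
    vignette: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_area_range
        if not (0 < lo <= hi < 0.9):
            raise InvalidParameterError(
                "lesion_area_range must satisfy 0 < min <= max < 0.9")
        if self.height < 8 or self.width < 8:
            raise InvalidParameterError("image too small")
        if self.texture_scale <= 0:
            raise InvalidParameterError("texture_scale must be positive")


def _rasterize_star(cfg: SynthConfig, center: tuple[float, float],
                    r0: float, harmonics) -> np.ndarray:
    rr, cc = np.mgrid[0:cfg.height, 0:cfg.width].astype(float)
    dy, dx = rr - center[0], cc - center[1]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_theta = r0 * (1.0 + cfg.boundary_roughness * harmonics(theta))
    return (rho <= r_theta).astype(np.uint8)


def generate_lesion_mask(cfg: SynthConfig) -> np.ndarray:
    """Generate a single-component irregular lesion mask.

    The blob's area fraction is drawn uniformly from
    ``cfg.lesion_area_range``; the initial radius is corrected once
    against the rasterised area so the realised fraction stays in range.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    lo, hi = cfg.lesion_area_range
    # largest mean radius whose rough border still fits inside the frame
    r0_cap = (min(h, w) / 2 - 2) / ((1.0 + cfg.boundary_roughness) * 1.05)
    feasible_hi = np.pi * r0_cap ** 2 / (h * w)
    if feasible_hi < lo:
        raise InvalidParameterError(
            f"lesion_area_range {cfg.lesion_area_range} infeasible for "
            f"{h}x{w} image (blob would not fit)")
    target_frac = rng.uniform(lo, min(hi, feasible_hi))
    r0 = np.sqrt(target_frac * h * w / np.pi)
    r_max = r0 * (1.0 + cfg.boundary_roughness) * 1.05

    cy = rng.uniform(r_max, h - r_max)
    cx = rng.uniform(r_max, w - r_max)

    # Fix the harmonic coefficients once, then evaluate on any theta grid;
    # normalise by the dense-grid peak so max |noise| = 1 exactly.
    coeffs = [(k, rng.uniform(0.5, 1.0) / k, rng.uniform(0, 2 * np.pi))
              for k in range(2, 7)]
    dense = np.linspace(-np.pi, np.pi, 2048)
    peak = np.abs(sum(a * np.cos(k * dense + p) for k, a, p in coeffs)).max()

    def _profile(theta: np.ndarray) -> np.ndarray:
        noise = np.zeros_like(theta)
        for k, amp, phase in coeffs:
            noise += amp * np.cos(k * theta + phase)
        return noise / peak if peak > 0 else noise

    # The rough border changes the area relative to pi*r0^2; rescale the
    # radius multiplicatively until the realised fraction is in range.
    mask = _rasterize_star(cfg, (cy, cx), r0, _profile)
    for _ in range(12):
        frac = mask.mean()
        if lo <= frac <= hi or frac == 0:
            break
        r0 = min(r0 * np.sqrt(target_frac / frac), r0_cap)
        mask = _rasterize_star(cfg, (cy, cx), r0, _profile)
    return mask


def _correlated_noise(shape, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-std Gaussian field with correlation length ``scale``."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=scale)
    std = smooth.std()
    return smooth / std if std > 0 else smooth


def _draw_hairs(img: np.ndarray, rng: np.random.Generator, n_hairs: int) -> None:
    """Dark quadratic Bezier strokes spanning the image, in place."""
    h, w = img.shape[:2]
    t = np.linspace(0.0, 1.0, 4 * max(h, w))
    for _ in range(n_hairs):
        # endpoints on opposite borders so strokes cross the frame
        if rng.random() < 0.5:
            p0 = np.array([rng.uniform(0, h), 0.0])
            p2 = np.array([rng.uniform(0, h), w - 1.0])
        else:
            p0 = np.array([0.0, rng.uniform(0, w)])
            p2 = np.array([h - 1.0, rng.uniform(0, w)])
        p1 = np.array([rng.uniform(0, h), rng.uniform(0, w)])
        pts = (np.outer((1 - t) ** 2, p0) + np.outer(2 * t * (1 - t), p1)
               + np.outer(t ** 2, p2))
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        shade = rng.uniform(20, 60)
        for dr in (0, 1):
            img[np.clip(rr + dr, 0, h - 1), cc] = shade


def _apply_vignette(img: np.ndarray) -> None:
    """Darken the corners outside the inscribed circle, in place."""
    h, w = img.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    rho = np.hypot(rr - (h - 1) / 2, cc - (w - 1) / 2)
    r_in = min(h, w) / 2
    fade = np.clip(1.0 - (rho - r_in) / (0.35 * r_in), 0.0, 1.0)
    img *= fade[..., None]


def render_image(mask: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Render an 8-bit RGB dermoscopy-like image for a lesion mask."""
    if mask.shape != (cfg.height, cfg.width):
        raise InvalidParameterError(
            f"mask shape {mask.shape} does not match config "
            f"({cfg.height}, {cfg.width})")
    # offset stream so image noise is independent of the mask draw
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    noise = _correlated_noise(mask.shape, cfg.texture_scale, rng) * _NOISE_STD

    img = np.empty((cfg.height, cfg.width, 3), dtype=float)
    img[:] = _SKIN_RGB
    img += noise[..., None]

    # smooth darkening: full contrast deep inside, ramping to zero at the
    # contour over _EDGE_FALLOFF_PX (the "blurred edge" look)
    inside_depth = ndimage.distance_transform_edt(mask.astype(bool))
    ramp = np.clip(inside_depth / _EDGE_FALLOFF_PX, 0.0, 1.0)
    img -= (cfg.contrast * _LESION_DARKEN * 255.0 * ramp)[..., None]

    if cfg.hair:
        _draw_hairs(img, rng, n_hairs=6)
    if cfg.vignette:
        _apply_vignette(img)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_pair(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: (image, mask) for one config."""
    mask = generate_lesion_mask(cfg)
    return render_image(mask, cfg), mask


def generate_dataset(cfg: SynthConfig, n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """``n`` image/mask pairs with per-item seeds derived from cfg.seed."""
    return [generate_pair(replace(cfg, seed=int(s)))
            for s in np.random.SeedSequence(cfg.seed).generate_state(n) % (2 ** 31)]
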