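"""Egg-style phenotype rendering.

Egg maculation is built from two thresholded noise-gradient layers (the
second smeared by a seeded random walk) combined with a base deposition into
a per-pixel pigment deposition field.  Coloration follows a two-axis pigment
model — deposition (amount of pigment) and ratio (biliverdin:protoporphyrin
mixture) — interpolated in CIELAB between a shell anchor and the two pure
pigment anchors, with a separate gene shifting the whole egg's luminance to
mimic exposure variation.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .imagega import Genome
from .pattern_animal import TargetImage, lab_to_rgb_clipped, mask_max_diameter

__all__ = [
    "EGG_TAGS",
    "EggPhenotypeSpec",
    "EggColorModel",
    "egg_maculation",
    "egg_pigment_to_lab",
    "render_egg",
    "egg_mask",
]


EGG_TAGS: tuple[str, ...] = (
    "mac1_win_x", "mac1_win_y", "mac1_win_scale",
    "mac1_shd_str", "mac1_thr_val", "mac1_dep_w",
    "mac2_win_x", "mac2_win_y", "mac2_win_scale",
    "mac2_shd_str", "mac2_thr_val", "mac2_dep_w",
    "mac2_wlk_steps", "mac2_wlk_len",
    "pig_base_dep", "pig_base_ratio", "pig_lum_shift",
)


@dataclasses.dataclass(frozen=True)
class EggPhenotypeSpec:
    """Gene-to-parameter mapping ranges for the egg renderer."""

    noise_resolution: int = 256
    sigma_range: tuple[float, float] = (0.3, 3.0)  # Gaussian SD along y
    window_frac: tuple[float, float] = (0.15, 0.6)
    shade_strength_max: float = 0.5
    walk_max_steps: int = 40
    walk_step_px: tuple[float, float] = (1.0, 5.0)
    lum_shift_L: float = 15.0   # +/- L units at the gene extremes

    @property
    def tags(self) -> tuple[str, ...]:
        return EGG_TAGS


@dataclasses.dataclass(frozen=True)
class EggColorModel:
    """CIELAB anchors of the deposition x pigment-ratio color surface.

    ``shell`` is the zero-deposition color; ``biliverdin`` and
    ``protoporphyrin`` are the full-deposition pure pigment colors.  The
    attainable colors are the bilinear interpolation surface between them,
    which is the model's avian color bound.
    """

    shell: tuple[float, float, float] = (93.0, 2.0, 12.0)
    biliverdin: tuple[float, float, float] = (55.0, -18.0, 2.0)
    protoporphyrin: tuple[float, float, float] = (35.0, 18.0, 30.0)
    deposition_exponent: float = 1.0
    ratio_range: tuple[float, float] = (0.0, 1.0)  # narrows the color range

    def __post_init__(self) -> None:
        if self.deposition_exponent <= 0:
            raise ValueError("deposition_exponent must be positive")
        lo, hi = self.ratio_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("ratio_range must be within [0, 1]")


def egg_pigment_to_lab(deposition, ratio, model: EggColorModel):
    """Map (deposition, ratio) in [0, 1]^2 to CIELAB.

    The pigment color interpolates between the protoporphyrin (ratio 0) and
    biliverdin (ratio 1) anchors; the output interpolates from the shell
    anchor toward that pigment color with deposition (raised to the model
    exponent).  Accepts scalars or arrays; returns an array with a trailing
    axis of 3.
    """
    dep = np.clip(np.asarray(deposition, dtype=float), 0.0, 1.0)
    rat = np.clip(np.asarray(ratio, dtype=float), 0.0, 1.0)
    lo, hi = model.ratio_range
    rat = lo + rat * (hi - lo)
    dep, rat = np.broadcast_arrays(dep, rat)
    shell = np.asarray(model.shell)
    bili = np.asarray(model.biliverdin)
    proto = np.asarray(model.protoporphyrin)
    pigment = proto + rat[..., None] * (bili - proto)
    w = dep[..., None] ** model.deposition_exponent
    return shell + w * (pigment - shell)


def _noise_gradient_field(resolution: int, sigma_range: tuple[float, float],
                          rng: np.random.Generator) -> np.ndarray:
    """White noise whose Gaussian blur SD increases along y, normalized to
    [0, 1] per row block so every row band keeps usable contrast."""
    base = rng.standard_normal((resolution, resolution))
    sigmas = np.linspace(sigma_range[0], sigma_range[1], 8)
    blurred = np.stack([ndimage.gaussian_filter(base, s) for s in sigmas])
    # per-level min-max normalization, then interpolate between levels by row
    mins = blurred.min(axis=(1, 2), keepdims=True)
    maxs = blurred.max(axis=(1, 2), keepdims=True)
    blurred = (blurred - mins) / np.maximum(maxs - mins, 1e-12)
    rows = np.linspace(0, len(sigmas) - 1, resolution)
    lower = np.floor(rows).astype(int)
    upper = np.minimum(lower + 1, len(sigmas) - 1)
    frac = (rows - lower)[:, None]
    return _row_interp(blurred, lower, upper, frac)


def _row_interp(levels: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                frac: np.ndarray) -> np.ndarray:
    res = levels.shape[1]
    out = np.empty((res, res))
    for r in range(res):
        out[r] = (1 - frac[r, 0]) * levels[lower[r], r] + frac[r, 0] * levels[upper[r], r]
    return out


def _maculation_layer(field: np.ndarray, out_shape: tuple[int, int],
                      win_x: float, win_y: float, scale: float,
                      shade_strength: float, threshold: float,
                      spec: EggPhenotypeSpec) -> np.ndarray:
    """Window, scale and shade the noise field, zeroing sub-threshold values.

    Returns a continuous [0, 1] layer (0 = no maculation)."""
    res = field.shape[0]
    lo, hi = spec.window_frac
    frac = lo + scale * (hi - lo)
    w = max(int(round(frac * res)), 2)
    x0 = int(round(win_x * (res - w)))
    y0 = int(round(win_y * (res - w)))
    crop = field[y0:y0 + w, x0:x0 + w]
    patch = sktransform.resize(crop, out_shape, order=1, mode="reflect",
                               anti_aliasing=True)
    patch = np.clip(patch, 0.0, 1.0)
    if shade_strength != 0.0:
        H, W = out_shape
        ramp = np.linspace(-0.5, 0.5, H)[:, None] * np.ones((1, W))
        patch = np.clip(patch + shade_strength * spec.shade_strength_max * ramp,
                        0.0, 1.0)
    if threshold >= 1.0:   # nothing can survive a full-range threshold
        return np.zeros(out_shape)
    return np.where(patch >= threshold, patch, 0.0)


def _random_walk_smear(layer: np.ndarray, steps: int, step_len: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Union of copies of the layer pasted along a seeded 8-neighbour random
    walk; with 0 steps the layer is returned unchanged."""
    if steps <= 0:
        return layer.copy()
    out = layer.copy()
    pos = np.zeros(2)
    dirs = np.array([(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                     if (dy, dx) != (0, 0)], dtype=float)
    for _ in range(steps):
        pos = pos + dirs[rng.integers(8)] * step_len
        dy, dx = int(round(pos[0])), int(round(pos[1]))
        shifted = np.roll(np.roll(layer, dy, axis=0), dx, axis=1)
        out = np.maximum(out, shifted)
    return out


def egg_maculation(genes: dict[str, float], out_shape: tuple[int, int],
                   rng: np.random.Generator,
                   spec: EggPhenotypeSpec = EggPhenotypeSpec()
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the two maculation layers and the combined deposition field.

    Layer 2 is additionally smeared by a seeded random walk.  The deposition
    field combines the base deposition with the two gene-weighted layers and
    is clamped to [0, 1].  Returns (layer1, layer2, deposition)."""
    field = _noise_gradient_field(spec.noise_resolution, spec.sigma_range, rng)
    layer1 = _maculation_layer(field, out_shape,
                               genes["mac1_win_x"], genes["mac1_win_y"],
                               genes["mac1_win_scale"], genes["mac1_shd_str"],
                               genes["mac1_thr_val"], spec)
    layer2 = _maculation_layer(field, out_shape,
                               genes["mac2_win_x"], genes["mac2_win_y"],
                               genes["mac2_win_scale"], genes["mac2_shd_str"],
                               genes["mac2_thr_val"], spec)
    steps = int(round(genes["mac2_wlk_steps"] * spec.walk_max_steps))
    lo, hi = spec.walk_step_px
    layer2 = _random_walk_smear(layer2, steps,
                                lo + genes["mac2_wlk_len"] * (hi - lo), rng)
    deposition = np.clip(
        genes["pig_base_dep"]
        + genes["mac1_dep_w"] * layer1
        + genes["mac2_dep_w"] * layer2,
        0.0, 1.0,
    )
    return layer1, layer2, deposition


def egg_mask(size: tuple[int, int] = (100, 130)) -> np.ndarray:
    """Default egg silhouette: an ovoid (wider at the bottom), (width,
    height) in pixels."""
    w, h = size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    t = (yy - cy) / (h / 2.0)          # -1 top .. +1 bottom
    rx = (w / 2.0) * (1.0 - 0.18 * np.clip(-t, 0, 1))  # narrower at the top
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / (h / 2.0)) ** 2 <= 1.0


def render_egg(genome: Genome, shape_mask: np.ndarray,
               spec: EggPhenotypeSpec, model: EggColorModel,
               seed: int = 0,
               rng: Optional[np.random.Generator] = None) -> TargetImage:
    """Render an egg genome: maculation -> per-pixel deposition -> pigment
    color model -> global luminance shift, masked to the egg silhouette.
    Deterministic given (genome, spec, model, seed)."""
    from .pattern_animal import _genome_rng  # shared seeding convention

    if shape_mask.dtype != bool:
        uniq = np.unique(shape_mask)
        if not np.all(np.isin(uniq, (0, 1))) and not np.all(np.isin(uniq, (0, 255))):
            raise ValueError("shape mask must be binary")
        shape_mask = shape_mask > (uniq.max() / 2)
    if genome.tags != spec.tags:
        raise ValueError("genome tag layout does not match the phenotype spec")
    if rng is None:
        rng = _genome_rng(genome, seed)
    g = genome.gene_map()

    _, _, deposition = egg_maculation(g, shape_mask.shape, rng, spec)
    lab = egg_pigment_to_lab(deposition, g["pig_base_ratio"], model)
    shift = (g["pig_lum_shift"] - 0.5) * 2.0 * spec.lum_shift_L
    lab[..., 0] = np.clip(lab[..., 0] + shift, 0.0, 100.0)

    rgb = lab_to_rgb_clipped(lab)
    rgb[~shape_mask] = 0.0
    return TargetImage(rgb=rgb, alpha=shape_mask.copy(), lab=lab,
                       max_diameter=mask_max_diameter(shape_mask),
                       genome_id=genome.id)
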