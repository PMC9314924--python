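"""Animal-style phenotype rendering.

A genome is turned into a target raster by sampling a window from a
precomputed Gray-Scott reaction-diffusion gamut, scaling/stretching and
shading it, thresholding to a maculation mask (optionally mirrored for
bilateral symmetry), colorizing background and maculation in CIELAB within
configurable channel limits, enhancing luminance contrast along the
maculation edge, and finally adding blurred speckling noise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import color as skcolor
from skimage import transform as sktransform

from .imagega import Genome

logger = logging.getLogger(__name__)

__all__ = [
    "RDGamut",
    "ColorSpaceLimits",
    "AnimalPhenotypeSpec",
    "TargetImage",
    "ANIMAL_TAGS",
    "build_rd_gamut",
    "sample_gamut",
    "binarize_and_mirror",
    "apply_speckling",
    "edge_enhance",
    "colorize",
    "render_target",
    "triangle_mask",
    "mask_max_diameter",
]


# Gene tag layout for the animal phenotype; every rendered feature is
# regulated by exactly one tagged gene.
ANIMAL_TAGS: tuple[str, ...] = (
    "pat_win_x", "pat_win_y", "pat_win_w", "pat_win_h",
    "pat_geo_scale", "pat_geo_stretch", "pat_geo_thr",
    "pat_shade_ang", "pat_shade_str",
    "col_bkg_lum", "col_bkg_a", "col_bkg_b",
    "col_mac_lum", "col_mac_a", "col_mac_b",
    "edge_dark_int", "edge_dark_exp", "edge_dark_sig",
    "edge_light_int", "edge_light_exp", "edge_light_sig",
    "spk_noise_den", "spk_noise_size",
)


@dataclasses.dataclass(frozen=True)
class ColorSpaceLimits:
    """Per-channel CIELAB ranges a coloration gene maps onto affinely."""

    L: tuple[float, float] = (0.0, 100.0)
    A: tuple[float, float] = (-60.0, 60.0)
    B: tuple[float, float] = (-10.0, 70.0)

    def __post_init__(self) -> None:
        for name in ("L", "A", "B"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} range must have min < max")

    def map_gene(self, channel: str, gene: float) -> float:
        lo, hi = getattr(self, channel)
        return lo + float(gene) * (hi - lo)


@dataclasses.dataclass(frozen=True)
class AnimalPhenotypeSpec:
    """Gene-to-parameter mapping ranges for the animal renderer."""

    symmetric: bool = False
    window_frac: tuple[float, float] = (0.1, 0.6)   # gamut window size range
    stretch_max: float = 8.0                        # Y-stretch at gene = 1
    shade_strength_max: float = 0.5                 # gradient amplitude
    edge_expansion_px: float = 10.0                 # band width at gene = 1
    edge_intensity_L: float = 25.0                  # L shift at gene = 1
    edge_sigma_px: tuple[float, float] = (0.25, 3.0)
    speckle_density_max: float = 0.05               # fraction of pixels
    speckle_sigma_px: tuple[float, float] = (0.5, 3.0)
    speckle_amplitude_L: float = 40.0

    @property
    def tags(self) -> tuple[str, ...]:
        return ANIMAL_TAGS


@dataclasses.dataclass
class TargetImage:
    """A rendered phenotype: sRGB raster + alpha mask + CIELAB planes."""

    rgb: np.ndarray          # (H, W, 3) float in [0, 1]
    alpha: np.ndarray        # (H, W) bool silhouette
    lab: np.ndarray          # (H, W, 3) CIELAB (D65)
    max_diameter: float      # largest pairwise distance within the silhouette
    genome_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.alpha.shape


# ---------------------------------------------------------------------------
# reaction-diffusion gamut


@dataclasses.dataclass(frozen=True)
class RDGamut:
    """Sheet of Gray-Scott textures spanning feed F (x) and kill k (y)."""

    texture: np.ndarray
    F_range: tuple[float, float]
    k_range: tuple[float, float]
    resolution: int
    iterations: int
    seed: int

    def __post_init__(self) -> None:
        t = self.texture
        if t.min() < 0 or t.max() > 1:
            raise ValueError("gamut texture must be normalized to [0, 1]")


_GAMUT_MEMO: dict[tuple, RDGamut] = {}


def build_rd_gamut(F_range: tuple[float, float] = (0.01, 0.09),
                   k_range: tuple[float, float] = (0.045, 0.070),
                   resolution: int = 256,
                   iterations: int = 5000,
                   seed: int = 0,
                   Du: float = 0.16,
                   Dv: float = 0.08,
                   dt: float = 1.0,
                   perturbation: float = 0.25,
                   cache_dir: Optional[Path] = None) -> RDGamut:
    """Integrate the Gray-Scott system on a grid with F varying along x and
    k along y, from a seeded noisy initial condition; returns the substrate
    (u) field min-max normalized to [0, 1].

    du/dt = Du lap(u) - u v^2 + F (1 - u)
    dv/dt = Dv lap(v) + u v^2 - (F + k) v

    With ``perturbation=0`` no activator is seeded and the field stays
    uniform; the degenerate normalization is handled as an all-zero (flat)
    texture.  Results are memoized in-process and, when ``cache_dir`` is
    given, cached to disk keyed by the full parameter set.
    """
    key = (F_range, k_range, resolution, iterations, seed, Du, Dv, dt,
           perturbation)
    if key in _GAMUT_MEMO:
        return _GAMUT_MEMO[key]

    cache_file = None
    if cache_dir is not None:
        digest = hashlib.sha1(repr(key).encode()).hexdigest()[:16]
        cache_file = Path(cache_dir) / f"rd_gamut_{digest}.npy"
        if cache_file.exists():
            gamut = RDGamut(np.load(cache_file), F_range, k_range,
                            resolution, iterations, seed)
            _GAMUT_MEMO[key] = gamut
            return gamut

    rng = np.random.default_rng(seed)
    res = resolution
    u = np.ones((res, res))
    v = np.zeros((res, res))
    if perturbation > 0:
        half = max(res // 8, 1)
        c = res // 2
        sl = slice(c - half, c + half)
        u[sl, sl] = 0.5
        v[sl, sl] = perturbation + 0.02 * rng.standard_normal((2 * half, 2 * half))

    F = np.broadcast_to(np.linspace(*F_range, res)[None, :], (res, res))
    k = np.broadcast_to(np.linspace(*k_range, res)[:, None], (res, res))

    with np.errstate(over="ignore", invalid="ignore"):  # divergence is caught below
        for _ in range(iterations):
            lu = (np.roll(u, 1, 0) + np.roll(u, -1, 0)
                  + np.roll(u, 1, 1) + np.roll(u, -1, 1) - 4.0 * u)
            lv = (np.roll(v, 1, 0) + np.roll(v, -1, 0)
                  + np.roll(v, 1, 1) + np.roll(v, -1, 1) - 4.0 * v)
            uvv = u * v * v
            u += dt * (Du * lu - uvv + F * (1.0 - u))
            v += dt * (Dv * lv + uvv - (F + k) * v)

    if not np.all(np.isfinite(u)):
        bad = np.argwhere(~np.isfinite(u))[0]
        fb = F[0, bad[1]]
        kb = k[bad[0], 0]
        raise ValueError(f"Gray-Scott integration diverged near F={fb:.4f}, "
                         f"k={kb:.4f}; narrow the parameter ranges")

    lo, hi = u.min(), u.max()
    texture = np.zeros_like(u) if hi - lo < 1e-12 else (u - lo) / (hi - lo)

    gamut = RDGamut(texture, F_range, k_range, resolution, iterations, seed)
    _GAMUT_MEMO[key] = gamut
    if cache_file is not None:
        cache_file.parent.mkdir(parents=True, exist_ok=True)
        np.save(cache_file, texture)
    return gamut


def sample_gamut(gamut: RDGamut, out_shape: tuple[int, int],
                 win_x: float, win_y: float, win_w: float, win_h: float,
                 stretch: float = 1.0, shade_angle: float = 0.0,
                 shade_strength: float = 0.0,
                 window_frac: tuple[float, float] = (0.1, 0.6)) -> np.ndarray:
    """Crop a gene-addressed window from the gamut, rescale to ``out_shape``
    (optionally stretching along Y for stripes) and add a linear luminance
    gradient of the given angle (radians) and strength.  Output in [0, 1]."""
    res = gamut.resolution
    lo, hi = window_frac
    wf = lo + float(win_w) * (hi - lo)
    hf = lo + float(win_h) * (hi - lo)
    w = max(int(round(wf * res)), 2)
    h = max(int(round(hf * res)), 2)
    x0 = int(round(float(win_x) * (res - w)))
    y0 = int(round(float(win_y) * (res - h)))
    crop = gamut.texture[y0:y0 + h, x0:x0 + w]

    if stretch > 1.0:
        rows = max(int(round(h / stretch)), 1)
        crop = crop[:rows, :]

    patch = sktransform.resize(crop, out_shape, order=1, mode="reflect",
                               anti_aliasing=True)
    patch = np.clip(patch, 0.0, 1.0)

    if shade_strength != 0.0:
        H, W = out_shape
        yy, xx = np.mgrid[0:H, 0:W]
        proj = (np.cos(shade_angle) * xx / max(W - 1, 1)
                + np.sin(shade_angle) * yy / max(H - 1, 1))
        span = proj.max() - proj.min()
        if span > 0:
            proj = (proj - proj.min()) / span
        patch = np.clip(patch + shade_strength * (proj - 0.5), 0.0, 1.0)
    return patch


def binarize_and_mirror(patch: np.ndarray, threshold: float,
                        symmetric: bool = False) -> np.ndarray:
    """Threshold to a maculation mask (True = maculation); if symmetric,
    reflect the left half onto the right about the vertical midline."""
    mask = patch >= threshold
    if symmetric:
        w = mask.shape[1]
        left = mask[:, : (w + 1) // 2]
        mask = np.concatenate([left, np.fliplr(mask[:, : w // 2])], axis=1)
    return mask


def colorize(mask: np.ndarray, color_genes: dict[str, float],
             limits: ColorSpaceLimits) -> np.ndarray:
    """Map the six coloration genes through their channel ranges and paint
    maculation/background pixels.  Returns an (H, W, 3) CIELAB image."""
    bkg = [limits.map_gene(ch, color_genes[f"col_bkg_{t}"])
           for ch, t in (("L", "lum"), ("A", "a"), ("B", "b"))]
    mac = [limits.map_gene(ch, color_genes[f"col_mac_{t}"])
           for ch, t in (("L", "lum"), ("A", "a"), ("B", "b"))]
    lab = np.empty(mask.shape + (3,), dtype=float)
    lab[...] = bkg
    lab[mask] = mac
    return lab


def edge_enhance(lab: np.ndarray, mask: np.ndarray,
                 genes: dict[str, float],
                 spec: AnimalPhenotypeSpec = AnimalPhenotypeSpec(),
                 limits: ColorSpaceLimits = ColorSpaceLimits()) -> np.ndarray:
    """Increase luminance contrast at the maculation edge: dark side gets
    darker, light side lighter, with independently gene-regulated intensity,
    band expansion and Gaussian sigma per side.  A/B planes are untouched."""
    out = lab.copy()
    if mask.all() or not mask.any():
        return out  # no boundary
    if genes["edge_dark_int"] == 0.0 and genes["edge_light_int"] == 0.0:
        return out

    mean_in = lab[..., 0][mask].mean()
    mean_out = lab[..., 0][~mask].mean()
    dark_side = mask if mean_in <= mean_out else ~mask
    sig_lo, sig_hi = spec.edge_sigma_px

    L = out[..., 0]
    for side, sign, prefix in ((dark_side, -1.0, "edge_dark"),
                               (~dark_side, +1.0, "edge_light")):
        intensity = genes[f"{prefix}_int"] * spec.edge_intensity_L
        if intensity == 0.0:
            continue
        width = max(genes[f"{prefix}_exp"] * spec.edge_expansion_px, 1.0)
        sigma = sig_lo + genes[f"{prefix}_sig"] * (sig_hi - sig_lo)
        dist = ndimage.distance_transform_edt(side)  # distance to boundary
        band = ((dist > 0) & (dist <= width)).astype(float)
        profile = ndimage.gaussian_filter(band, sigma)
        L[side] = L[side] + sign * intensity * profile[side]
    out[..., 0] = np.clip(L, limits.L[0], limits.L[1])
    return out


def apply_speckling(lab: np.ndarray, density: float, size: float,
                    rng: np.random.Generator,
                    spec: AnimalPhenotypeSpec = AnimalPhenotypeSpec(),
                    limits: ColorSpaceLimits = ColorSpaceLimits()) -> np.ndarray:
    """Add salt-type noise at gene-scaled density, Gaussian-blurred at
    gene-scaled sigma, to the luminance plane.  Density 0 is the identity."""
    out = lab.copy()
    frac = density * spec.speckle_density_max
    n = int(round(frac * lab.shape[0] * lab.shape[1]))
    if n == 0:
        return out
    field = np.zeros(lab.shape[:2])
    flat = rng.choice(field.size, size=n, replace=False)
    field.flat[flat] = spec.speckle_amplitude_L
    sig_lo, sig_hi = spec.speckle_sigma_px
    field = ndimage.gaussian_filter(field, sig_lo + size * (sig_hi - sig_lo))
    out[..., 0] = np.clip(out[..., 0] + field, limits.L[0], limits.L[1])
    return out


# ---------------------------------------------------------------------------
# shape masks


def triangle_mask(size: tuple[int, int] = (150, 75)) -> np.ndarray:
    """Isosceles triangle silhouette, ``size`` given as (width, height)."""
    w, h = size
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    # apex at top center, base along the bottom row
    t = yy / max(h - 1, 1)
    half = 0.5 * t * (w - 1)
    mask[np.abs(xx - (w - 1) / 2.0) <= half] = True
    mask[0, (w - 1) // 2] = True
    return mask


def mask_max_diameter(mask: np.ndarray) -> float:
    """Largest pairwise pixel distance within a silhouette (exact, via the
    convex hull of the mask's pixel coordinates)."""
    pts = np.argwhere(mask).astype(float)
    if len(pts) == 0:
        raise ValueError("empty mask")
    if len(pts) == 1:
        return 1.0
    try:
        hull = pts[ConvexHull(pts).vertices]
    except Exception:  # degenerate (collinear) masks
        hull = pts
    # +1: diameters are measured across pixel extents, not centers
    return float(pdist(hull).max()) + 1.0


# ---------------------------------------------------------------------------
# full pipeline


def lab_to_rgb_clipped(lab: np.ndarray) -> np.ndarray:
    """CIELAB -> sRGB (D65); out-of-gamut channels are clipped with a logged
    count."""
    import warnings

    with warnings.catch_warnings():
        # skimage warns per conversion about out-of-gamut clipping; we count
        # and log it ourselves
        warnings.filterwarnings("ignore", message=".*color space resulted in.*")
        rgb = skcolor.lab2rgb(lab)
    n_out = int(np.count_nonzero((rgb < 0) | (rgb > 1)))
    if n_out:
        logger.debug("lab->srgb conversion clipped %d channel values", n_out)
    return np.clip(rgb, 0.0, 1.0)


def _genome_rng(genome: Genome, seed: int) -> np.random.Generator:
    digest = hashlib.sha1(genome.id.encode()).digest()[:4]
    return np.random.default_rng([seed, int.from_bytes(digest, "little")])


def render_target(genome: Genome, shape_mask: np.ndarray,
                  spec: AnimalPhenotypeSpec, limits: ColorSpaceLimits,
                  gamut: RDGamut, seed: int = 0) -> TargetImage:
    """Render a genome into a target: sample -> binarize/mirror -> colorize
    -> edge enhance -> speckle, masked to the shape silhouette.  Deterministic
    given (genome, spec, gamut, seed)."""
    if shape_mask.dtype != bool:
        uniq = np.unique(shape_mask)
        if not np.all(np.isin(uniq, (0, 1))) and not np.all(np.isin(uniq, (0, 255))):
            raise ValueError("shape mask must be binary")
        shape_mask = shape_mask > (uniq.max() / 2)
    if genome.tags != spec.tags:
        raise ValueError("genome tag layout does not match the phenotype spec")
    g = genome.gene_map()
    rng = _genome_rng(genome, seed)
    out_shape = shape_mask.shape

    stretch = 1.0 + g["pat_geo_stretch"] * (spec.stretch_max - 1.0)
    patch = sample_gamut(
        gamut, out_shape,
        g["pat_win_x"], g["pat_win_y"], g["pat_win_w"], g["pat_win_h"],
        stretch=stretch,
        shade_angle=g["pat_shade_ang"] * 2.0 * np.pi,
        shade_strength=g["pat_shade_str"] * spec.shade_strength_max,
        window_frac=spec.window_frac,
    )
    # pattern scale: resample the patch about its center by a gene-set zoom
    zoom = 0.5 + g["pat_geo_scale"] * 1.5   # 0.5x .. 2x
    if abs(zoom - 1.0) > 1e-9:
        patch = sktransform.rescale(patch, zoom, order=1, mode="reflect",
                                    anti_aliasing=zoom < 1.0)
        patch = sktransform.resize(patch, out_shape, order=1, mode="reflect",
                                   anti_aliasing=True)
        patch = np.clip(patch, 0.0, 1.0)

    mac = binarize_and_mirror(patch, g["pat_geo_thr"], spec.symmetric)
    lab = colorize(mac, g, limits)
    lab = edge_enhance(lab, mac, g, spec, limits)
    lab = apply_speckling(lab, g["spk_noise_den"], g["spk_noise_size"],
                          rng, spec, limits)

    rgb = lab_to_rgb_clipped(lab)
    rgb[~shape_mask] = 0.0
    return TargetImage(rgb=rgb, alpha=shape_mask.copy(), lab=lab,
                       max_diameter=mask_max_diameter(shape_mask),
                       genome_id=genome.id)
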