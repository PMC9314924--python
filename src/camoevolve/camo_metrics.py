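"""Camouflage quantification.

Two families of metrics: CIELAB statistics (absolute differences of channel
means and standard deviations between the target and its local background —
a circle of diameter ``factor`` times the target's maximum diameter with the
target excluded) and GabRat edge disruption (the ratio of "false" edge
energy running across the target outline to the "true" energy parallel to
it, measured with a bank of quadrature Gabor filters).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

logger = logging.getLogger(__name__)

__all__ = [
    "CamoMetrics",
    "LocalRegion",
    "local_region",
    "lab_stats",
    "camo_diffs",
    "gabrat",
    "gabor_bank",
    "measure_slide",
]


@dataclasses.dataclass(frozen=True)
class CamoMetrics:
    """Per-target camouflage metrics (all Delta values are magnitudes)."""

    dmu_L: float
    dmu_A: float
    dmu_B: float
    dsig_L: float
    dsig_A: float
    dsig_B: float
    gabrat_L: float = float("nan")
    gabrat_A: float = float("nan")
    gabrat_B: float = float("nan")

    @property
    def dmu_norm(self) -> float:
        return float(np.sqrt(self.dmu_L ** 2 + self.dmu_A ** 2 + self.dmu_B ** 2))

    @property
    def dsig_norm(self) -> float:
        return float(np.sqrt(self.dsig_L ** 2 + self.dsig_A ** 2 + self.dsig_B ** 2))

    @property
    def gabrat_mean(self) -> float:
        vals = [self.gabrat_L, self.gabrat_A, self.gabrat_B]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class LocalRegion:
    """Background sampling region around a placed target."""

    pixels: np.ndarray        # (H, W) bool, True = in region
    n_pixels: int
    clipped: bool             # circle ran off the slide edge
    diameter: float


def local_region(slide_shape: tuple[int, int], target_mask: np.ndarray,
                 factor: float = 2.0) -> LocalRegion:
    """Circle of diameter ``factor`` x target max diameter centered on the
    target centroid, with all target pixels excluded and clipped to the
    slide bounds (flagged when clipping occurs).

    ``target_mask`` is a full-slide boolean mask of the placed target.
    """
    from .pattern_animal import mask_max_diameter

    if target_mask.shape != tuple(slide_shape):
        raise ValueError("target mask must cover the full slide")
    if not target_mask.any():
        raise ValueError("target mask is empty")
    ys, xs = np.nonzero(target_mask)
    cy, cx = ys.mean(), xs.mean()
    diameter = factor * mask_max_diameter(target_mask)
    r = diameter / 2.0

    H, W = slide_shape
    yy, xx = np.ogrid[0:H, 0:W]
    circle = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    clipped = bool(cy - r < 0 or cx - r < 0 or cy + r > H - 1 or cx + r > W - 1)
    if clipped:
        logger.debug("local region clipped at slide bounds")
    region = circle & ~target_mask
    n = int(region.sum())
    if n == 0:
        raise ValueError("local background region is empty (target fills the circle)")
    return LocalRegion(pixels=region, n_pixels=n, clipped=clipped,
                       diameter=diameter)


def lab_stats(pixels: np.ndarray, lab: np.ndarray) -> tuple[float, ...]:
    """Channel means and population standard deviations over a pixel set.

    ``pixels``: boolean mask; ``lab``: (H, W, 3) CIELAB planes.
    Returns (muL, muA, muB, sigL, sigA, sigB).
    """
    if not pixels.any():
        raise ValueError("empty pixel set")
    vals = lab[pixels]  # (n, 3)
    mu = vals.mean(axis=0)
    sig = vals.std(axis=0)  # population (n) form
    return (float(mu[0]), float(mu[1]), float(mu[2]),
            float(sig[0]), float(sig[1]), float(sig[2]))


def camo_diffs(target_stats: tuple[float, ...],
               local_stats: tuple[float, ...],
               signed: bool = False) -> tuple[float, ...]:
    """Per-channel differences of means and SDs (absolute by default)."""
    d = np.asarray(target_stats, dtype=float) - np.asarray(local_stats, dtype=float)
    if not signed:
        d = np.abs(d)
    return tuple(float(x) for x in d)


# ---------------------------------------------------------------------------
# GabRat


def gabor_bank(sigma: float, n_orientations: int,
               wavelength: Optional[float] = None
               ) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Quadrature Gabor kernels.

    Returns, per orientation, ``(edge_angle, even, odd)`` where
    ``edge_angle`` is the orientation (radians, mod pi) of the *edges* the
    pair responds to (perpendicular to the wave vector).  The even kernel is
    DC-corrected so responses are invariant to global offsets.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if wavelength is None:
        wavelength = 2.0 * sigma
    half = int(np.ceil(3.0 * sigma))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    bank = []
    for i in range(n_orientations):
        theta = np.pi * i / n_orientations       # wave-vector direction
        rot = xx * np.cos(theta) + yy * np.sin(theta)
        env = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
        even = env * np.cos(2.0 * np.pi * rot / wavelength)
        odd = env * np.sin(2.0 * np.pi * rot / wavelength)
        even -= even.mean()
        edge_angle = (theta + np.pi / 2.0) % np.pi
        bank.append((edge_angle, even, odd))
    return bank


def _outline_and_tangents(mask: np.ndarray, sigma: float
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Outline pixels of a mask and the local outline tangent angle (mod pi),
    estimated from the gradient of the Gaussian-smoothed mask."""
    outline = mask & ~ndimage.binary_erosion(mask)
    if not outline.any():
        raise ValueError("mask has no outline")
    smooth = ndimage.gaussian_filter(mask.astype(float), max(sigma, 1.0))
    gy, gx = np.gradient(smooth)
    normal = np.arctan2(gy, gx)
    tangent = (normal + np.pi / 2.0) % np.pi
    return outline, tangent


def _angle_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest difference between orientations (mod pi)."""
    d = np.abs(a - b) % np.pi
    return np.minimum(d, np.pi - d)


def gabrat(plane: np.ndarray, target_mask: np.ndarray, sigma: float = 3.0,
           n_orientations: int = 4, *, naive: bool = False) -> float:
    """GabRat edge disruption of one channel plane, in [0, 1].

    For every outline pixel the quadrature Gabor energy (even^2 + odd^2) of
    the orientation parallel to the local outline tangent is the "true" edge
    response; the maximal orthogonal-component energy over the bank is the
    "false" response.
    GabRat is the mean of false / (false + true); pixels with no edge signal
    either way contribute the neutral value 0.5 (logged).  Higher values mean
    a more disrupted (harder to segment) outline.

    ``naive=True`` evaluates the filters by direct per-pixel dot products at
    the outline pixels only — the slow reference path used to validate the
    FFT filtering.
    """
    plane = np.asarray(plane, dtype=float)
    bank = gabor_bank(sigma, n_orientations)
    outline, tangent = _outline_and_tangents(target_mask, sigma)
    ys, xs = np.nonzero(outline)
    half = (bank[0][1].shape[0] - 1) // 2

    energies = np.empty((len(bank), len(ys)))
    if naive:
        padded = np.pad(plane, half)
        for bi, (_, even, odd) in enumerate(bank):
            for pi, (y, x) in enumerate(zip(ys, xs)):
                win = padded[y:y + 2 * half + 1, x:x + 2 * half + 1]
                e = float((win * even).sum())
                o = float((win * odd).sum())
                energies[bi, pi] = e * e + o * o
    else:
        # filter only a zero-padded window around the outline; every outline
        # pixel's kernel support lies inside it, so this equals filtering the
        # full (zero-padded) plane
        oy, ox = ys.min() - half, xs.min() - half
        hgt = ys.max() - ys.min() + 2 * half + 1
        wid = xs.max() - xs.min() + 2 * half + 1
        sub = np.zeros((hgt, wid))
        sy0, sx0 = max(oy, 0), max(ox, 0)
        sy1 = min(oy + hgt, plane.shape[0])
        sx1 = min(ox + wid, plane.shape[1])
        sub[sy0 - oy:sy1 - oy, sx0 - ox:sx1 - ox] = plane[sy0:sy1, sx0:sx1]
        for bi, (_, even, odd) in enumerate(bank):
            # kernels are symmetric/antisymmetric under 180-degree rotation,
            # so correlation == convolution up to the odd kernel's sign,
            # which the squared energy discards
            e = fftconvolve(sub, even[::-1, ::-1], mode="same")
            o = fftconvolve(sub, odd[::-1, ::-1], mode="same")
            ev = e[ys - oy, xs - ox]
            ov = o[ys - oy, xs - ox]
            energies[bi] = ev * ev + ov * ov

    edge_angles = np.array([b[0] for b in bank])
    tan = tangent[ys, xs]
    diffs = _angle_diff(edge_angles[:, None], tan[None, :])  # (n_orient, n_pix)
    true_e = energies[np.argmin(diffs, axis=0), np.arange(len(ys))]
    # orthogonal component of the quadrature energy: weight by sin^2
    false_e = (energies * np.sin(edge_angles[:, None] - tan[None, :]) ** 2).max(axis=0)

    total = true_e + false_e
    ratio = np.full(len(ys), 0.5)
    ok = total > 1e-12
    ratio[ok] = false_e[ok] / total[ok]
    if not ok.all():
        logger.debug("gabrat: %d outline pixels had no edge signal; neutral 0.5 used",
                     int((~ok).sum()))
    return float(ratio.mean())


def measure_slide(lab: np.ndarray, target_mask: np.ndarray,
                  factor: float = 2.0, sigma: float = 3.0,
                  n_orientations: int = 4,
                  compute_gabrat: bool = True) -> CamoMetrics:
    """All metrics for one placed target on a slide given full-slide CIELAB
    planes and the target's full-slide mask.  A/B planes are z-scored before
    Gabor filtering so channel scale does not dominate the edge metric."""
    region = local_region(lab.shape[:2], target_mask, factor)
    t_stats = lab_stats(target_mask, lab)
    b_stats = lab_stats(region.pixels, lab)
    d = camo_diffs(t_stats, b_stats)

    g = [float("nan")] * 3
    if compute_gabrat:
        for i in range(3):
            plane = lab[..., i]
            if i > 0:
                sd = plane.std()
                plane = (plane - plane.mean()) / sd if sd > 1e-12 else plane * 0.0
            g[i] = gabrat(plane, target_mask, sigma, n_orientations)
    return CamoMetrics(dmu_L=d[0], dmu_A=d[1], dmu_B=d[2],
                       dsig_L=d[3], dsig_A=d[4], dsig_B=d[5],
                       gabrat_L=g[0], gabrat_A=g[1], gabrat_B=g[2])
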