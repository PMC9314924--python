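"""Shared formats, configuration and fixtures.

Chromosome logs are plain text, one file per generation: a header line with
the tab-separated tag labels, then one line per member carrying id, lifeline
flag, fitness, rank and the gene values at 6 decimal places.  Run
configuration round-trips losslessly through YAML.  A synthetic-background
generator (spatially correlated CIELAB noise) stands in for photographed
habitats so no external data is needed.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .imagega import GAConfig, Genome, Population
from .pattern_animal import ColorSpaceLimits

__all__ = [
    "write_chromosomes",
    "read_chromosomes",
    "SynthBackground",
    "synth_background",
    "ObserverConfig",
    "RunConfig",
    "box1_config",
    "atomic_write_text",
]


def atomic_write_text(path: Path, text: str) -> None:
    """Write text to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# chromosome files


def write_chromosomes(path: Path, pop: Population) -> None:
    """Save a population as a tab-separated text file (see module docstring)."""
    lines = ["\t".join(("id", "lifeline", "fitness", "rank") + pop.tags)]
    for i, m in enumerate(pop.members):
        fit = "" if pop.fitnesses is None else f"{pop.fitnesses[i]:.6f}"
        rank = "" if pop.ranks is None else str(int(pop.ranks[i]))
        genes = "\t".join(f"{g:.6f}" for g in m.genes)
        lines.append("\t".join([m.id, "1" if m.lifeline else "0", fit, rank, genes]))
    atomic_write_text(Path(path), "\n".join(lines) + "\n")


def read_chromosomes(path: Path, generation: int = 0,
                     expected_tags: Optional[Sequence[str]] = None) -> Population:
    """Load a chromosome file back into a Population.

    Raises on malformed lines (with the line number), on gene values outside
    [0, 1], and on a header that does not match ``expected_tags``."""
    text = Path(path).read_text().rstrip("\n")
    lines = text.split("\n")
    header = lines[0].split("\t")
    if len(header) < 5 or header[:4] != ["id", "lifeline", "fitness", "rank"]:
        raise ValueError(f"{path}: malformed chromosome header")
    tags = tuple(header[4:])
    if expected_tags is not None:
        for got, want in zip(tags, tuple(expected_tags)):
            if got != want:
                raise ValueError(f"{path}: header tag {got!r} does not match "
                                 f"expected layout tag {want!r}")
        if len(tags) != len(tuple(expected_tags)):
            raise ValueError(f"{path}: header has {len(tags)} tags, expected "
                             f"{len(tuple(expected_tags))}")

    members, fits, ranks = [], [], []
    for ln, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 4 + len(tags):
            raise ValueError(f"{path}: line {ln} has {len(fields)} fields, "
                             f"expected {4 + len(tags)}")
        gid, lifeline, fit, rank = fields[:4]
        genes = np.array([float(x) for x in fields[4:]])
        if np.any(genes < 0) or np.any(genes > 1):
            raise ValueError(f"{path}: line {ln} has gene values outside [0, 1]")
        members.append(Genome(genes=genes, tags=tags, id=gid,
                              lifeline=lifeline == "1"))
        fits.append(float(fit) if fit else np.nan)
        ranks.append(int(rank) if rank else 0)

    pop = Population(members=members, generation=generation)
    if not any(np.isnan(fits)):
        pop.fitnesses = np.asarray(fits)
    if all(r > 0 for r in ranks):
        pop.ranks = np.asarray(ranks)
    return pop


# ---------------------------------------------------------------------------
# synthetic backgrounds


@dataclasses.dataclass
class SynthBackground:
    """A generated background with both sRGB raster and CIELAB planes."""

    rgb: np.ndarray   # (H, W, 3) float in [0, 1]
    lab: np.ndarray   # (H, W, 3)
    name: str = "synthetic"


def synth_background(size: tuple[int, int], mean_lab: tuple[float, float, float],
                     texture_scale: float, rng: np.random.Generator,
                     sd_lab: tuple[float, float, float] = (12.0, 8.0, 8.0),
                     name: str = "synthetic") -> SynthBackground:
    """Spatially correlated noise texture with exact per-channel CIELAB means
    and SDs.

    ``texture_scale`` is the requested autocorrelation length in pixels (the
    lag at which correlation falls to 1/e); Gaussian-filtered white noise has
    autocorrelation exp(-lag^2 / (4 sigma^2)), whose 1/e point is 2 sigma, so
    sigma = scale / 2.  ``size`` is (width, height)."""
    w, h = size
    sigma = max(texture_scale, 1e-6) / 2.0
    lab = np.empty((h, w, 3))
    for c in range(3):
        g = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
        g = (g - g.mean()) / max(g.std(), 1e-12)
        lab[..., c] = mean_lab[c] + sd_lab[c] * g
    lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)
    from .pattern_animal import lab_to_rgb_clipped

    return SynthBackground(rgb=lab_to_rgb_clipped(lab), lab=lab, name=name)


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class ObserverConfig:
    """Parameters of the simulated observer."""

    baseline_ms: float = 4000.0
    w_mean: float = 4.0          # weight on the normalized mean difference
    w_sd: float = 2.0            # weight on the normalized SD difference
    w_gabrat: float = 1.0        # weight on mean GabRat (reduces saliency)
    noise_sigma: float = 0.3     # log-normal multiplicative noise
    learning_rate: float = 0.0   # per-slide multiplicative time shrink
    lapse_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_ms <= 0:
            raise ValueError("baseline_ms must be positive")
        if not 0.0 <= self.lapse_probability <= 1.0:
            raise ValueError("lapse_probability must be in [0, 1]")


@dataclasses.dataclass
class RunConfig:
    """Full description of an evolution run; round-trips through YAML."""

    ga: GAConfig = dataclasses.field(default_factory=GAConfig)
    observer: ObserverConfig = dataclasses.field(default_factory=ObserverConfig)
    limits: ColorSpaceLimits = dataclasses.field(default_factory=ColorSpaceLimits)
    phenotype: str = "animal"                 # "animal" | "egg"
    symmetric: bool = False
    target_size: tuple[int, int] = (150, 75)  # (width, height) px
    crop_size: tuple[int, int] = (1478, 1130)
    slide_duration_ms: float = 15000.0
    hybrid_threshold_ms: float = 600.0
    fitness_method: str = "hybrid"            # hybrid | response | capture | location
    generations: int = 15
    warmup_targets: int = 2
    local_region_factor: float = 2.0
    compute_gabrat: bool = True
    gabrat_sigma: float = 3.0
    gabrat_orientations: int = 4
    gamut_resolution: int = 256
    gamut_iterations: int = 5000
    n_backgrounds: int = 8
    background_texture_scale: float = 12.0
    outdir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype not in ("animal", "egg"):
            raise ValueError("phenotype must be 'animal' or 'egg'")
        if self.fitness_method not in ("hybrid", "response", "capture", "location"):
            raise ValueError(f"unknown fitness method {self.fitness_method!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["limits"] = {"L": list(self.limits.L), "A": list(self.limits.A),
                       "B": list(self.limits.B)}
        d["target_size"] = list(self.target_size)
        d["crop_size"] = list(self.crop_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ga" in d:
            d["ga"] = GAConfig(**d["ga"])
        if "observer" in d:
            d["observer"] = ObserverConfig(**d["observer"])
        if "limits" in d:
            lim = d["limits"]
            d["limits"] = ColorSpaceLimits(L=tuple(lim["L"]), A=tuple(lim["A"]),
                                           B=tuple(lim["B"]))
        for key in ("target_size", "crop_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: Path) -> None:
        atomic_write_text(Path(path), yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def box1_config(seed: int = 0, outdir: Optional[str] = None) -> RunConfig:
    """The packaged demo configuration: 24 triangle targets (150 x 75 px)
    evolved for 15 generations with CIELAB limits L 0..100, A -60..60,
    B -10..70, 1478 x 1130 px background crops, 15 s slides, hybrid fitness
    with the 600 ms threshold and two warm-up targets per generation."""
    return RunConfig(
        ga=GAConfig(N=24, seed=seed),
        limits=ColorSpaceLimits(L=(0.0, 100.0), A=(-60.0, 60.0), B=(-10.0, 70.0)),
        phenotype="animal",
        target_size=(150, 75),
        crop_size=(1478, 1130),
        slide_duration_ms=15000.0,
        hybrid_threshold_ms=600.0,
        fitness_method="hybrid",
        generations=15,
        warmup_targets=2,
        local_region_factor=2.0,
        outdir=outdir,
        seed=seed,
    )
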