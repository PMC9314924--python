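"""Headless visual-search predation: slide construction, a simulated
observer with the original timing semantics (response vs capture, 15 s
timeout, 600 ms hybrid rule), fitness scoring and the generational loop.

The simulated observer stands in for a human player: a conspicuousness
score built from the camouflage metrics sets the median of a log-normal
detection-time distribution; more conspicuous targets are found faster.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import imagega
from .camo_metrics import CamoMetrics, measure_slide
from .imagega import GAConfig, Genome, Population
from .io_interface import (ObserverConfig, RunConfig, SynthBackground,
                           atomic_write_text, synth_background,
                           write_chromosomes)
from .pattern_animal import (ANIMAL_TAGS, AnimalPhenotypeSpec, TargetImage,
                             build_rd_gamut, render_target, triangle_mask)
from .pattern_egg import (EGG_TAGS, EggColorModel, EggPhenotypeSpec, egg_mask,
                          render_egg)

logger = logging.getLogger(__name__)

__all__ = [
    "Slide",
    "ObservationResult",
    "Observer",
    "build_slides",
    "simulate_observation",
    "survival_time",
    "run_generation",
    "run_evolution",
    "GenerationRecord",
    "EvolutionHistory",
    "make_renderer",
]


@dataclasses.dataclass
class Slide:
    """One background crop with a single placed target."""

    lab: np.ndarray             # (H, W, 3) composited CIELAB planes
    target_mask: np.ndarray     # (H, W) bool, placed target silhouette
    target_id: str
    x: int                      # target center, 0-based px from the left
    y: int                      # target center, 0-based px from the top
    rotation: float             # counter-clockwise degrees
    display_order: int
    duration_ms: float = 15000.0
    background_name: str = ""
    rgb: Optional[np.ndarray] = None  # composited sRGB, kept only when saving


@dataclasses.dataclass
class ObservationResult:
    """Timing record of one slide."""

    response_time: float   # ms to first cursor movement
    capture_time: float    # ms to the click on the target
    timed_out: bool
    click_xy: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0 <= self.response_time <= self.capture_time):
            raise ValueError("need 0 <= response_time <= capture_time")


class Observer:
    """Simulated observer with optional per-slide learning state."""

    def __init__(self, cfg: ObserverConfig):
        self.cfg = cfg
        self.slides_seen = 0

    def reset(self) -> None:
        self.slides_seen = 0

    def conspicuousness(self, m: CamoMetrics) -> float:
        c = (self.cfg.w_mean * m.dmu_norm / 100.0
             + self.cfg.w_sd * m.dsig_norm / 50.0)
        if self.cfg.w_gabrat != 0.0 and np.isfinite(m.gabrat_mean):
            c -= self.cfg.w_gabrat * m.gabrat_mean
        return float(c)


def _center_crop(img: np.ndarray, crop_size: tuple[int, int],
                 name: str = "") -> np.ndarray:
    """Center crop to (width, height); error when the source is smaller."""
    cw, ch = crop_size
    H, W = img.shape[:2]
    if W < cw or H < ch:
        raise ValueError(f"background {name or '<array>'} is {W}x{H} px, "
                         f"smaller than the {cw}x{ch} crop")
    y0 = (H - ch) // 2
    x0 = (W - cw) // 2
    return img[y0:y0 + ch, x0:x0 + cw]


def _rotate_sprite(target: TargetImage, angle_deg: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the target's CIELAB planes and alpha (counter-clockwise,
    expanding the canvas)."""
    lab = ndimage.rotate(target.lab, angle_deg, reshape=True, order=1,
                         mode="constant", cval=0.0)
    alpha = ndimage.rotate(target.alpha.astype(float), angle_deg, reshape=True,
                           order=1, mode="constant", cval=0.0) > 0.5
    return lab, alpha


def build_slides(backgrounds: Sequence[SynthBackground],
                 targets: Sequence[TargetImage],
                 rng: np.random.Generator,
                 crop_size: tuple[int, int] = (1478, 1130),
                 duration_ms: float = 15000.0,
                 keep_rgb: bool = False) -> list[Slide]:
    """One slide per target: targets are shown in a random sequence, each on
    a center crop of a randomly assigned background, placed uniformly at a
    position keeping the rotated target fully inside, with uniform 0-360
    degree rotation."""
    if not backgrounds:
        raise ValueError("at least one background required")
    order = rng.permutation(len(targets))
    slides = []
    for disp, ti in enumerate(order):
        target = targets[ti]
        bg = backgrounds[rng.integers(len(backgrounds))]
        lab = _center_crop(bg.lab, crop_size, bg.name).copy()
        rgb = _center_crop(bg.rgb, crop_size, bg.name).copy() if keep_rgb else None

        angle = float(rng.uniform(0.0, 360.0))
        s_lab, s_alpha = _rotate_sprite(target, angle)
        sh, sw = s_alpha.shape
        ch, cw = lab.shape[:2]
        if sw > cw - 2 or sh > ch - 2:
            raise ValueError("rotated target does not fit inside the crop")
        # 1-px margin keeps the target strictly inside the crop border
        x0 = int(rng.integers(1, cw - sw))
        y0 = int(rng.integers(1, ch - sh))

        mask = np.zeros((ch, cw), dtype=bool)
        mask[y0:y0 + sh, x0:x0 + sw] = s_alpha
        lab[y0:y0 + sh, x0:x0 + sw][s_alpha] = s_lab[s_alpha]
        if rgb is not None:
            from .pattern_animal import lab_to_rgb_clipped
            s_rgb = lab_to_rgb_clipped(s_lab)
            rgb[y0:y0 + sh, x0:x0 + sw][s_alpha] = s_rgb[s_alpha]

        slides.append(Slide(lab=lab, target_mask=mask, target_id=target.genome_id,
                            x=x0 + sw // 2, y=y0 + sh // 2, rotation=angle,
                            display_order=disp, duration_ms=duration_ms,
                            background_name=bg.name, rgb=rgb))
    return slides


def simulate_observation(slide: Slide, metrics: CamoMetrics,
                         observer: Observer,
                         rng: np.random.Generator) -> ObservationResult:
    """Draw a detection for one slide.

    The response (first movement) time is log-normal with median
    baseline * exp(-conspicuousness), shrunk multiplicatively by accumulated
    learning, and capped at the slide duration (timeout).  Capture adds a
    gamma-distributed click-execution delay with median about 300 ms."""
    cfg = observer.cfg
    limit = slide.duration_ms

    lapsed = rng.random() < cfg.lapse_probability
    c = observer.conspicuousness(metrics)
    learning = (1.0 - cfg.learning_rate) ** observer.slides_seen
    median = cfg.baseline_ms * np.exp(-c) * learning
    noise = np.exp(cfg.noise_sigma * rng.standard_normal()) if cfg.noise_sigma > 0 else 1.0
    response = median * noise
    # click-execution delay: gamma(k=3), median ~ 300 ms
    delay = float(rng.gamma(3.0, 300.0 / 2.674))

    observer.slides_seen += 1
    if lapsed or response >= limit:
        return ObservationResult(response_time=limit, capture_time=limit,
                                 timed_out=True, click_xy=(-1, -1))
    capture = min(response + delay, limit)
    return ObservationResult(response_time=float(response),
                             capture_time=float(capture), timed_out=False,
                             click_xy=(slide.x, slide.y))


def survival_time(obs: ObservationResult, method: str = "hybrid",
                  hybrid_threshold_ms: float = 600.0,
                  duration_ms: float = 15000.0) -> float:
    """Fitness in ms from an observation.

    ``hybrid`` returns the response time unless capture - response exceeds
    the threshold (600 ms by default), in which case the capture time is
    used; ``response``/``capture`` return their fields; ``location`` scores
    the capture time (the left/right-click correctness channel is resolved at
    observation time).  Timeouts return the slide duration."""
    if method not in ("hybrid", "response", "capture", "location"):
        raise ValueError(f"unknown fitness method {method!r}")
    if obs.timed_out:
        return float(duration_ms)
    if method == "response":
        return obs.response_time
    if method in ("capture", "location"):
        return obs.capture_time
    if obs.capture_time - obs.response_time > hybrid_threshold_ms:
        return obs.capture_time
    return obs.response_time


# ---------------------------------------------------------------------------
# rendering plumbing


def make_renderer(cfg: RunConfig):
    """Return (tags, render(genome, seed) -> TargetImage) for the configured
    phenotype."""
    if cfg.phenotype == "animal":
        spec = AnimalPhenotypeSpec(symmetric=cfg.symmetric)
        mask = triangle_mask(cfg.target_size)
        gamut = build_rd_gamut(resolution=cfg.gamut_resolution,
                               iterations=cfg.gamut_iterations, seed=cfg.seed)

        def render(genome: Genome, seed: int) -> TargetImage:
            return render_target(genome, mask, spec, cfg.limits, gamut, seed)

        return ANIMAL_TAGS, render

    spec = EggPhenotypeSpec()
    model = EggColorModel()
    mask = egg_mask(cfg.target_size)

    def render(genome: Genome, seed: int) -> TargetImage:
        return render_egg(genome, mask, spec, model, seed)

    return EGG_TAGS, render


# ---------------------------------------------------------------------------
# generational loop


@dataclasses.dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    median_fitness: float
    diversity: float
    mean_dmu: float            # mean of dmu_L + dmu_A + dmu_B over members
    top_third_dmu: float       # same, over the top-ranked third
    mean_gabrat: float
    fitnesses: np.ndarray
    metrics: list[CamoMetrics]


@dataclasses.dataclass
class EvolutionHistory:
    records: list[GenerationRecord]
    final_population: Population


def run_generation(pop: Population, backgrounds: Sequence[SynthBackground],
                   cfg: RunConfig, observer: Observer,
                   rng: np.random.Generator,
                   render=None, outdir: Optional[Path] = None
                   ) -> tuple[np.ndarray, np.ndarray, list[CamoMetrics]]:
    """Evaluate one generation.

    Renders every member plus the warm-up targets (random genomes shown
    first, excluded from the population), builds slides, simulates the
    observer and measures camouflage.  Returns (fitnesses, display_order,
    metrics), all indexed by member position.  When ``outdir`` is given,
    chromosomes, coordinates and metrics are written there."""
    if render is None:
        _, render = make_renderer(cfg)

    targets = [render(m, cfg.seed) for m in pop.members]
    warmups = []
    for w in range(cfg.warmup_targets):
        genes = rng.random(len(pop.tags))
        g = Genome(genes=genes, tags=pop.tags, id=f"warmup-{pop.generation}-{w}")
        warmups.append(render(g, cfg.seed))

    member_slides = build_slides(backgrounds, targets, rng,
                                 crop_size=cfg.crop_size,
                                 duration_ms=cfg.slide_duration_ms,
                                 keep_rgb=outdir is not None)
    warm_slides = build_slides(backgrounds, warmups, rng,
                               crop_size=cfg.crop_size,
                               duration_ms=cfg.slide_duration_ms) if warmups else []

    # warm-ups run first; their results never enter the fitness list
    session = warm_slides + sorted(member_slides, key=lambda s: s.display_order)
    id_to_index = {m.id: i for i, m in enumerate(pop.members)}
    fitnesses = np.empty(pop.N)
    display_order = np.empty(pop.N, dtype=int)
    member_metrics: list[Optional[CamoMetrics]] = [None] * pop.N
    rows = []

    for si, slide in enumerate(session):
        metrics = measure_slide(slide.lab, slide.target_mask,
                                factor=cfg.local_region_factor,
                                sigma=cfg.gabrat_sigma,
                                n_orientations=cfg.gabrat_orientations,
                                compute_gabrat=cfg.compute_gabrat)
        obs = simulate_observation(slide, metrics, observer, rng)
        fit = survival_time(obs, cfg.fitness_method, cfg.hybrid_threshold_ms,
                            cfg.slide_duration_ms)
        is_warmup = slide.target_id.startswith("warmup-")
        if not is_warmup:
            i = id_to_index[slide.target_id]
            fitnesses[i] = fit
            display_order[i] = si
            member_metrics[i] = metrics
        rows.append({"generation": pop.generation, "id": slide.target_id,
                     "slide": si, "x": slide.x, "y": slide.y,
                     "rotation": round(slide.rotation, 3),
                     **{k: round(v, 6) for k, v in metrics.as_dict().items()},
                     "fitness": round(fit, 3), "warmup": int(is_warmup)})

    if outdir is not None:
        outdir = Path(outdir)
        gen = pop.generation
        write_chromosomes(outdir / f"chromosomes_gen{gen:03d}.txt", pop)
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
        atomic_write_text(outdir / f"metrics_gen{gen:03d}.csv", buf.getvalue())
        _save_target_pngs(outdir, gen, targets, member_slides)

    return fitnesses, display_order, member_metrics  # type: ignore[return-value]


def _save_target_pngs(outdir: Path, gen: int, targets: Sequence[TargetImage],
                      slides: Sequence[Slide]) -> None:
    from PIL import Image

    tdir = outdir / f"targets_gen{gen:03d}"
    tdir.mkdir(parents=True, exist_ok=True)
    for t in targets:
        rgba = np.dstack([t.rgb, t.alpha.astype(float)])
        img = Image.fromarray((rgba * 255).astype(np.uint8), mode="RGBA")
        img.save(tdir / f"target_{t.genome_id}.png")
    sdir = outdir / f"slides_gen{gen:03d}"
    sdir.mkdir(parents=True, exist_ok=True)
    for s in slides:
        if s.rgb is not None:
            Image.fromarray((s.rgb * 255).astype(np.uint8)).save(
                sdir / f"slide_{s.display_order:02d}_{s.target_id}.png")


def run_evolution(cfg: RunConfig,
                  backgrounds: Optional[Sequence[SynthBackground]] = None,
                  observers: Optional[Sequence[Observer]] = None
                  ) -> EvolutionHistory:
    """Run the full loop: evaluate, rank, turn over, for ``cfg.generations``
    evaluated generations (a run of G generations performs G evaluations and
    G - 1 turnovers; G = 0 still evaluates the initial population once).

    ``observers`` may hold several observers to alternate between
    generations (offsetting search-image learning); by default a single
    observer from the config is reused."""
    rng = np.random.default_rng(cfg.seed)
    tags, render = make_renderer(cfg)
    ga = cfg.ga

    if backgrounds is None:
        backgrounds = default_backgrounds(cfg, rng)
    if observers is None:
        observers = [Observer(cfg.observer)]

    outdir = Path(cfg.outdir) if cfg.outdir else None
    pop = imagega.init_population(ga, tags, rng)
    records: list[GenerationRecord] = []
    n_evals = max(cfg.generations, 1)

    for gen in range(n_evals):
        observer = observers[gen % len(observers)]
        observer.reset()
        fitnesses, disp, metrics = run_generation(pop, backgrounds, cfg,
                                                  observer, rng, render,
                                                  outdir)
        pop.set_fitness(fitnesses, reverse=ga.reverse_ranking, tie_key=disp)
        records.append(_summarize(pop, metrics))
        if outdir is not None:
            write_chromosomes(outdir / f"chromosomes_gen{gen:03d}.txt", pop)
        if gen < n_evals - 1 and cfg.generations > 0:
            pop = imagega.next_generation(pop, ga, rng)

    if outdir is not None:
        _write_history_csv(outdir / "history.csv", records)
    return EvolutionHistory(records=records, final_population=pop)


def default_backgrounds(cfg: RunConfig,
                        rng: np.random.Generator) -> list[SynthBackground]:
    """Synthetic habitat set: correlated-noise textures with varied mean
    CIELAB colors, sized 10% larger than the crop."""
    cw, ch = cfg.crop_size
    size = (int(cw * 1.1) + 2, int(ch * 1.1) + 2)
    bgs = []
    for i in range(cfg.n_backgrounds):
        mean = (float(rng.uniform(35, 65)), float(rng.uniform(-15, 15)),
                float(rng.uniform(0, 35)))
        bgs.append(synth_background(size, mean, cfg.background_texture_scale,
                                    rng, name=f"synth-{i}"))
    return bgs


def _summarize(pop: Population, metrics: Sequence[CamoMetrics]) -> GenerationRecord:
    fit = np.asarray(pop.fitnesses)
    dmu = np.array([m.dmu_L + m.dmu_A + m.dmu_B for m in metrics])
    gab = np.array([m.gabrat_mean for m in metrics])
    third = max(pop.N // 3, 1)
    top = np.argsort(pop.ranks)[:third]
    return GenerationRecord(
        generation=pop.generation,
        best_fitness=float(fit.max()),
        median_fitness=float(np.median(fit)),
        diversity=imagega.genetic_diversity(pop),
        mean_dmu=float(dmu.mean()),
        top_third_dmu=float(dmu[top].mean()),
        mean_gabrat=float(np.nanmean(gab)) if np.isfinite(gab).any() else float("nan"),
        fitnesses=fit,
        metrics=list(metrics),
    )


def _write_history_csv(path: Path, records: Sequence[GenerationRecord]) -> None:
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["generation", "best_fitness", "median_fitness",
                     "diversity", "mean_dmu", "top_third_dmu", "mean_gabrat"])
    for r in records:
        writer.writerow([r.generation, round(r.best_fitness, 3),
                         round(r.median_fitness, 3), round(r.diversity, 6),
                         round(r.mean_dmu, 4), round(r.top_third_dmu, 4),
                         round(r.mean_gabrat, 6) if np.isfinite(r.mean_gabrat) else ""])
    atomic_write_text(path, buf.getvalue())
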