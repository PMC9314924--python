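"""Decimal-gene genetic algorithm tailored to small psychophysics populations.

Genomes are fixed-length vectors of decimal genes in [0, 1].  Each gene carries
a three-level hierarchical tag (``group_subgroup_channel``, e.g. ``col_mac_lum``)
that groups genes by function and defines which genes are "equivalent" for the
structural mutation operators (swap / scramble / duplication).

The generational scheme uses overlapping generations: the top fraction of a
ranked population survives unaltered and breeds (twice, with fresh random
pairings) to fill the remaining slots with mutated offspring.  Recent elites
carry a *lifeline*: if a previous top individual falls into the deletion pool
on the next (noisy) ranking, it displaces a planned offspring slot instead of
dying.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Genome",
    "Population",
    "GAConfig",
    "init_population",
    "rank_population",
    "select_survivors",
    "apply_lifeline",
    "crossover",
    "mutate_point",
    "mutate_structural",
    "adaptive_rate",
    "next_generation",
    "genetic_diversity",
    "overdispersed_diversity",
]


def split_tag(tag: str) -> tuple[str, str, str]:
    """Split a three-level tag into (group, subgroup, channel)."""
    parts = tag.split("_")
    if len(parts) != 3:
        raise ValueError(f"tag {tag!r} is not a three-level 'group_subgroup_channel' label")
    return parts[0], parts[1], parts[2]


def _check_tags(tags: Sequence[str]) -> tuple[str, ...]:
    tags = tuple(tags)
    if not tags:
        raise ValueError("tag layout must be non-empty")
    if len(set(tags)) != len(tags):
        raise ValueError("tag labels must be unique")
    for t in tags:
        split_tag(t)
    return tags


@dataclasses.dataclass
class Genome:
    """A fixed-length vector of decimal genes with hierarchical tags."""

    genes: np.ndarray
    tags: tuple[str, ...]
    id: str
    lifeline: bool = False

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)
        self.tags = _check_tags(self.tags)
        if self.genes.ndim != 1 or len(self.genes) != len(self.tags):
            raise ValueError("genes and tags must be 1-D and the same length")
        if np.any(self.genes < 0) or np.any(self.genes > 1):
            raise ValueError("gene values must lie in [0, 1]")

    def copy(self, *, id: Optional[str] = None, lifeline: Optional[bool] = None) -> "Genome":
        return Genome(
            genes=self.genes.copy(),
            tags=self.tags,
            id=self.id if id is None else id,
            lifeline=self.lifeline if lifeline is None else lifeline,
        )

    def gene(self, tag: str) -> float:
        """Value of the gene carrying ``tag``."""
        return float(self.genes[self.tags.index(tag)])

    def gene_map(self) -> dict[str, float]:
        return {t: float(g) for t, g in zip(self.tags, self.genes)}


@dataclasses.dataclass
class Population:
    """Fixed-size set of genomes with generation index, fitnesses and ranks."""

    members: list[Genome]
    generation: int = 0
    fitnesses: Optional[np.ndarray] = None
    ranks: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("population needs at least 2 members")
        layout = self.members[0].tags
        if any(m.tags != layout for m in self.members):
            raise ValueError("all members must share the same tag layout")

    @property
    def N(self) -> int:
        return len(self.members)

    @property
    def tags(self) -> tuple[str, ...]:
        return self.members[0].tags

    def gene_matrix(self) -> np.ndarray:
        """(N, G) matrix of gene values, rows in member order."""
        return np.stack([m.genes for m in self.members])

    def is_ranked(self) -> bool:
        return self.ranks is not None

    def set_fitness(self, fitnesses: Sequence[float], *, reverse: bool = False,
                    tie_key: Optional[Sequence[int]] = None) -> None:
        """Record fitnesses and derive ranks in one step."""
        self.fitnesses = np.asarray(fitnesses, dtype=float)
        if len(self.fitnesses) != self.N:
            raise ValueError("one fitness value per member required")
        self.ranks = rank_population(self.fitnesses, reverse=reverse, tie_key=tie_key)

    def by_rank(self) -> list[Genome]:
        """Members sorted best (rank 1) first."""
        if self.ranks is None:
            raise ValueError("population is not ranked")
        order = np.argsort(self.ranks)
        return [self.members[i] for i in order]


@dataclasses.dataclass
class GAConfig:
    """Parameters of the genetic algorithm.

    Defaults mirror the toolbox defaults: N=24, one third survives and breeds,
    three lifelines, per-gene point-mutation rate 0.1 with step 0.05, low
    (0.02) per-event structural mutation probabilities, and adaptive rate
    modulation (diversity- and rank-responsive) enabled.
    """

    N: int = 24
    survive_fraction: float = 1.0 / 3.0
    lifeline_count: int = 3
    base_mutation_rate: float = 0.1
    mutation_step: float = 0.05
    swap_rate: float = 0.02
    scramble_rate: float = 0.02
    duplication_rate: float = 0.02
    adaptive: bool = True
    c_diversity: float = 1.0
    c_fitness: float = 0.5
    rate_min: float = 0.01
    rate_max: float = 0.5
    reverse_ranking: bool = False
    init_mode: str = "overdispersed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be at least 2")
        if not 0.0 < self.survive_fraction < 1.0:
            raise ValueError("survive_fraction must be in (0, 1)")
        if self.lifeline_count < 0 or self.lifeline_count > int(np.floor(self.N * self.survive_fraction)):
            raise ValueError("lifeline_count must be in [0, floor(N * survive_fraction)]")
        for name in ("base_mutation_rate", "mutation_step", "swap_rate",
                     "scramble_rate", "duplication_rate", "rate_min", "rate_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.init_mode not in ("overdispersed", "random", "gaussian", "custom"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    @property
    def n_survivors(self) -> int:
        return int(np.rint(self.N * self.survive_fraction))


# ---------------------------------------------------------------------------
# initialization


def init_population(cfg: GAConfig, tag_layout: Sequence[str],
                    rng: Optional[np.random.Generator] = None,
                    custom: Optional[np.ndarray] = None) -> Population:
    """Create generation-0 population.

    The default ``overdispersed`` mode places, at every gene position, the N
    values k/(N+1) for k = 1..N in an independent random permutation, so the
    sorted values at each position are evenly spaced with interval 1/(N+1) and
    never touch the boundaries.  Alternative modes: ``random`` (uniform),
    ``gaussian`` (mean 0.5, sd 0.15, reflected into [0, 1]) and ``custom``
    (explicit (N, G) matrix).
    """
    tags = _check_tags(tag_layout)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    N, G = cfg.N, len(tags)

    if cfg.init_mode == "overdispersed":
        ladder = np.arange(1, N + 1, dtype=float) / (N + 1)
        mat = np.stack([rng.permutation(ladder) for _ in range(G)], axis=1)
    elif cfg.init_mode == "random":
        mat = rng.random((N, G))
    elif cfg.init_mode == "gaussian":
        mat = _reflect01(rng.normal(0.5, 0.15, size=(N, G)))
    else:  # custom
        if custom is None:
            raise ValueError("init_mode 'custom' requires a custom matrix")
        mat = np.asarray(custom, dtype=float)
        if mat.shape != (N, G):
            raise ValueError(f"custom matrix must have shape ({N}, {G}), got {mat.shape}")
        if np.any(mat < 0) or np.any(mat > 1):
            raise ValueError("custom matrix values must lie in [0, 1]")

    members = [Genome(genes=mat[i], tags=tags, id=f"0-{i}") for i in range(N)]
    return Population(members=members, generation=0)


# ---------------------------------------------------------------------------
# ranking and selection


def rank_population(fitnesses: Sequence[float], reverse: bool = False,
                    tie_key: Optional[Sequence[int]] = None) -> np.ndarray:
    """Rank fitnesses; rank 1 = longest survival time (highest fitness).

    With ``reverse=True`` (conspicuousness mode) rank 1 is the *shortest*
    survival time.  Ties are broken deterministically: the member with the
    later display order (larger ``tie_key``) wins the better rank.
    """
    f = np.asarray(fitnesses, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("fitness values must be finite")
    n = len(f)
    tie = np.arange(n) if tie_key is None else np.asarray(tie_key)
    if len(tie) != n:
        raise ValueError("tie_key must have one entry per member")
    keyed = sorted(range(n), key=lambda i: (f[i] if reverse else -f[i], -tie[i]))
    ranks = np.empty(n, dtype=int)
    for pos, i in enumerate(keyed):
        ranks[i] = pos + 1
    return ranks


def select_survivors(pop: Population, cfg: GAConfig) -> tuple[list[Genome], list[Genome]]:
    """Split a ranked population into (breeders/survivors, deleted).

    Breeder count = round(N * survive_fraction); breeders are exactly the
    top-ranked members.
    """
    if not pop.is_ranked():
        raise ValueError("population must be ranked before selection")
    ordered = pop.by_rank()
    k = cfg.n_survivors
    return ordered[:k], ordered[k:]


def apply_lifeline(prev_elites: set[str], deleted: list[Genome],
                   n_offspring_slots: int) -> tuple[list[Genome], int]:
    """Rescue previous elites that fell into the deletion pool.

    Each rescued genome consumes one planned offspring slot (lowest-ranked
    slot first, i.e. we simply generate fewer offspring); rescued genomes
    re-enter unmutated.  Returns (rescued genomes, remaining offspring slots).
    """
    rescued = [g for g in deleted if g.id in prev_elites]
    assert len(rescued) <= n_offspring_slots, "more elites to rescue than offspring slots"
    return rescued, n_offspring_slots - len(rescued)


# ---------------------------------------------------------------------------
# variation operators


def crossover(parent_a: Genome, parent_b: Genome, rng: np.random.Generator,
              child_id: str = "") -> Genome:
    """Incomplete crossover: per-gene randomly weighted average of the parents.

    g_i = w_i * a_i + (1 - w_i) * b_i with w_i ~ U[0, 1] drawn independently
    per gene, so every offspring gene lies within the parental interval.
    """
    if parent_a.tags != parent_b.tags:
        raise ValueError("parents must share the same tag layout")
    w = rng.random(len(parent_a.genes))
    genes = w * parent_a.genes + (1.0 - w) * parent_b.genes
    return Genome(genes=genes, tags=parent_a.tags, id=child_id)


def _reflect01(x: np.ndarray) -> np.ndarray:
    """Fold values back into [0, 1] by reflection at the boundaries."""
    x = np.mod(np.asarray(x, dtype=float), 2.0)
    return np.where(x > 1.0, 2.0 - x, x)


def mutate_point(genome: Genome, rate: float, step: float,
                 rng: np.random.Generator) -> Genome:
    """Point mutation: each gene flips with probability ``rate`` by a
    sign-symmetric perturbation of magnitude ``step * K`` with K ~ Poisson(1).

    Out-of-range results are reflected back into [0, 1] rather than clipped,
    so probability mass does not pile up at the boundaries.
    """
    if not (0.0 <= rate <= 1.0 and 0.0 <= step <= 1.0):
        raise ValueError("rate and step must be in [0, 1]")
    out = genome.copy()
    if rate == 0.0:
        return out
    G = len(out.genes)
    hit = rng.random(G) < rate
    k = rng.poisson(1.0, size=G)
    sign = np.where(rng.random(G) < 0.5, -1.0, 1.0)
    delta = np.where(hit, sign * step * k, 0.0)
    out.genes = _reflect01(out.genes + delta)
    return out


def equivalence_classes(tags: Sequence[str]) -> list[list[int]]:
    """Gene index sets that are tag-equivalent for structural mutations.

    Genes are equivalent when they share the same channel label (third tag
    level), e.g. ``col_mac_lum`` and ``col_bkg_lum``; only classes with at
    least two members are returned.
    """
    by_channel: dict[str, list[int]] = {}
    for i, t in enumerate(tags):
        by_channel.setdefault(split_tag(t)[2], []).append(i)
    return [idx for idx in by_channel.values() if len(idx) >= 2]


def mutate_structural(genome: Genome, cfg: GAConfig,
                      rng: np.random.Generator) -> Genome:
    """Swap / scramble / duplication between tag-equivalent genes.

    - swap: exchange the values of two equivalent genes
    - scramble: randomly permute the values within one equivalence class
    - duplication: target gene becomes ``w*source + (1-w)*target``, w ~ U[0,1]

    Each event fires independently with its configured (low) probability.
    """
    out = genome.copy()
    classes = equivalence_classes(out.tags)
    do_swap = rng.random() < cfg.swap_rate
    do_scramble = rng.random() < cfg.scramble_rate
    do_dup = rng.random() < cfg.duplication_rate
    if not (do_swap or do_scramble or do_dup):
        return out
    if not classes:
        warnings.warn("structural mutation requested but tag layout has no "
                      "equivalent gene pairs; no-op", stacklevel=2)
        return out
    if do_swap:
        cls = classes[rng.integers(len(classes))]
        i, j = rng.choice(cls, size=2, replace=False)
        out.genes[i], out.genes[j] = out.genes[j], out.genes[i]
    if do_scramble:
        cls = classes[rng.integers(len(classes))]
        out.genes[cls] = rng.permutation(out.genes[cls])
    if do_dup:
        cls = classes[rng.integers(len(classes))]
        src, tgt = rng.choice(cls, size=2, replace=False)
        w = rng.random()
        out.genes[tgt] = w * out.genes[src] + (1.0 - w) * out.genes[tgt]
    return out


# ---------------------------------------------------------------------------
# diversity and adaptive rates


def genetic_diversity(pop: Population) -> float:
    """Mean over gene positions of the mean pairwise absolute difference."""
    mat = pop.gene_matrix()
    N = mat.shape[0]
    if N < 2:
        raise ValueError("diversity needs at least 2 members")
    diff = np.abs(mat[:, None, :] - mat[None, :, :])  # (N, N, G)
    return float(diff.sum() / (N * (N - 1)) / mat.shape[1])


def overdispersed_diversity(N: int) -> float:
    """Expected diversity D0 of an overdispersed population of size N.

    For values k/(N+1), k=1..N, the mean pairwise absolute difference is
    exactly 1/3 independent of N.
    """
    return 1.0 / 3.0


def adaptive_rate(pop: Population, cfg: GAConfig) -> np.ndarray:
    """Per-individual point-mutation rates.

    rate_i = clamp(base * (1 + c_d * (1 - D/D0)) * (1 + c_f * u_i),
                   rate_min, rate_max)

    where D is the current genetic diversity, D0 the overdispersed reference
    diversity, and u_i = (rank_i - 1)/(N - 1) the relative unfitness, so
    fitter individuals mutate less.  With ``adaptive=False`` every individual
    gets the base rate.
    """
    if not cfg.adaptive:
        return np.full(pop.N, cfg.base_mutation_rate)
    if not pop.is_ranked():
        raise ValueError("adaptive rates require a ranked population")
    D = genetic_diversity(pop)
    D0 = overdispersed_diversity(pop.N)
    unfitness = (np.asarray(pop.ranks, dtype=float) - 1.0) / max(pop.N - 1, 1)
    rates = (cfg.base_mutation_rate
             * (1.0 + cfg.c_diversity * (1.0 - D / D0))
             * (1.0 + cfg.c_fitness * unfitness))
    return np.clip(rates, cfg.rate_min, cfg.rate_max)


# ---------------------------------------------------------------------------
# generation turnover


def _pairings(breeders: list[int], rng: np.random.Generator) -> list[tuple[int, int]]:
    """One mating round: random permutation pairing; each breeder appears once
    as the focal parent.  An odd last breeder draws a random second partner."""
    perm = list(rng.permutation(len(breeders)))
    partner = {}
    for a, b in zip(perm[0::2], perm[1::2]):
        partner[a] = b
        partner[b] = a
    if len(perm) % 2 == 1:
        last = perm[-1]
        others = [i for i in range(len(breeders)) if i != last]
        partner[last] = int(rng.choice(others))
    return [(breeders[i], breeders[partner[i]]) for i in range(len(breeders))]


def next_generation(pop: Population, cfg: GAConfig,
                    rng: np.random.Generator) -> Population:
    """Produce the next population from an evaluated, ranked one.

    Survivors (top round(N * survive_fraction) ranks) carry over with genes
    unaltered.  Breeders mate in rounds — each round a fresh random pairing
    producing one offspring per breeder — until the N - survivors offspring
    slots are filled; offspring undergo crossover, point mutation and
    structural mutation.  Previous-generation elites falling in the deletion
    pool displace offspring slots (lifeline).  The new generation's top
    ``lifeline_count`` members are flagged as the next elites.
    """
    if pop.N != cfg.N:
        raise ValueError("population size does not match config")
    survivors, deleted = select_survivors(pop, cfg)
    prev_elites = {m.id for m in pop.members if m.lifeline}
    n_slots = pop.N - len(survivors)
    rescued, n_offspring = apply_lifeline(prev_elites, deleted, n_slots)

    rates = adaptive_rate(pop, cfg)
    rate_of = {m.id: r for m, r in zip(pop.members, rates)}

    gen = pop.generation + 1
    idx = list(range(len(survivors)))
    offspring: list[Genome] = []
    while len(offspring) < n_offspring:
        for a, b in _pairings(idx, rng):
            if len(offspring) >= n_offspring:
                break
            child = crossover(survivors[a], survivors[b], rng,
                              child_id=f"{gen}-o{len(offspring)}")
            rate = 0.5 * (rate_of[survivors[a].id] + rate_of[survivors[b].id])
            child = mutate_point(child, rate, cfg.mutation_step, rng)
            child = mutate_structural(child, cfg, rng)
            offspring.append(child)

    members = ([m.copy(lifeline=False) for m in survivors]
               + [m.copy(lifeline=False) for m in rescued]
               + offspring)
    # survivors are ordered by rank, so the first lifeline_count are the elites
    for m in members[:cfg.lifeline_count]:
        m.lifeline = True
    return Population(members=members, generation=gen)
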