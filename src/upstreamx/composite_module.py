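"""Composite-module search: a weighted combination of at most 10 motifs
co-occurring inside a 200-300 bp promoter window that best separates the
Yes (differentially expressed) from the No (background) promoters.

A module is scored on a promoter as the best window placement:

    score(promoter) = max over window start s of
        sum over members  weight * min(#hits of that motif in [s, s+W), cap)

with per-member saturation cap in {1, 2, 3}. Separation quality is the
one-sided Wilcoxon rank-sum p-value (Yes > No); the fitness maximized by the
genetic algorithm is -log10(p) minus a small complexity penalty per member
to keep modules parsimonious.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .site_scan import SiteHit

logger = logging.getLogger("upstreamx")

MAX_MEMBERS = 10
W_MIN, W_MAX = 200, 300
MAX_COUNT_CHOICES = (1, 2, 3)
COMPLEXITY_PENALTY = 0.05
#: largest per-group size for which the rank-sum p is computed by exact
#: enumeration (C(16, 8) = 12870 assignments at the boundary)
EXACT_N = 8


@dataclass(frozen=True)
class ModuleMember:
    pwm_name: str
    weight: float
    max_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError(f"weight {self.weight} outside [0, 1]")
        if self.max_count not in MAX_COUNT_CHOICES:
            raise ValueError(f"max_count {self.max_count} not in 1..3")


@dataclass(frozen=True)
class CompositeModule:
    members: tuple[ModuleMember, ...]
    window_width: int
    fitness: float = float("nan")
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= MAX_MEMBERS:
            raise ValueError(
                f"module must have 1..{MAX_MEMBERS} members, "
                f"got {len(self.members)}"
            )
        if not W_MIN <= self.window_width <= W_MAX:
            raise ValueError(
                f"window width {self.window_width} outside "
                f"[{W_MIN}, {W_MAX}]"
            )

    @property
    def member_names(self) -> set[str]:
        return {m.pwm_name for m in self.members}


@dataclass
class GaParams:
    """Genetic-algorithm hyperparameters (defaults are the shipped search
    configuration)."""

    population: int = 50
    generations: int = 100
    tournament_k: int = 3
    crossover_p: float = 0.5
    mutation_p: float = 0.1
    elitism: int = 1
    max_members: int = MAX_MEMBERS
    complexity_penalty: float = COMPLEXITY_PENALTY

    def validate(self) -> None:
        if not 1 <= self.max_members <= MAX_MEMBERS:
            raise ValueError(
                f"max_members must be 1..{MAX_MEMBERS}, got {self.max_members}"
            )
        if self.population < 2 or self.generations < 1:
            raise ValueError("population >= 2 and generations >= 1 required")


# ---------------------------------------------------------------------------
# Module scoring
# ---------------------------------------------------------------------------

HitIndex = Mapping[str, Mapping[str, np.ndarray]]


def index_hits(hits: Iterable[SiteHit],
               genes: Iterable[str] | None = None) -> dict[str, dict[str, np.ndarray]]:
    """promoter -> pwm -> sorted array of hit starts (both strands pooled)."""
    idx: dict[str, dict[str, list[int]]] = {}
    if genes is not None:
        for g in genes:
            idx[g] = {}
    for h in hits:
        idx.setdefault(h.gene_id, {}).setdefault(h.pwm_name, []).append(h.start)
    return {
        g: {p: np.array(sorted(starts), dtype=np.int64)
            for p, starts in by_pwm.items()}
        for g, by_pwm in idx.items()
    }


def module_score(promoter_hits: Mapping[str, np.ndarray],
                 module: CompositeModule,
                 promoter_length: int = 1100) -> float:
    """Best-window co-occurrence score of one promoter.

    The maximum over continuous window starts is attained with the window's
    left edge at a hit start (counts only change there), so only those
    candidates (clamped into [0, length - W]) are evaluated.
    """
    W = module.window_width
    member_starts = [promoter_hits.get(m.pwm_name) for m in module.members]
    candidates: set[int] = {0}
    lo_max = max(promoter_length - W, 0)
    for starts in member_starts:
        if starts is not None and len(starts):
            candidates.update(int(min(s, lo_max)) for s in starts)
    best = 0.0
    for s in candidates:
        total = 0.0
        for m, starts in zip(module.members, member_starts):
            if starts is None or not len(starts):
                continue
            n = int(np.searchsorted(starts, s + W, side="left")
                    - np.searchsorted(starts, s, side="left"))
            total += m.weight * min(n, m.max_count)
        best = max(best, total)
    return best


def score_set(hit_index: HitIndex, genes: Sequence[str],
              module: CompositeModule,
              promoter_length: int = 1100) -> np.ndarray:
    return np.array([
        module_score(hit_index.get(g, {}), module, promoter_length)
        for g in genes
    ])


# ---------------------------------------------------------------------------
# Wilcoxon fitness
# ---------------------------------------------------------------------------

def _exact_rank_sum_p(yes: np.ndarray, no: np.ndarray) -> float:
    """Exact one-sided p (Yes tends larger) by enumerating all assignments
    of the pooled values into a Yes-sized subset. Ties are handled by
    working on the values directly via the Mann-Whitney U statistic."""
    pooled = np.concatenate([yes, no])
    n_yes = len(yes)

    def u_stat(a: np.ndarray, b: np.ndarray) -> float:
        diff = a[:, None] - b[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    observed = u_stat(yes, no)
    count = 0
    total = 0
    all_idx = set(range(len(pooled)))
    for comb in combinations(range(len(pooled)), n_yes):
        a = pooled[list(comb)]
        b = pooled[list(all_idx - set(comb))]
        if u_stat(a, b) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def wilcoxon_fitness(yes_scores: Sequence[float],
                     no_scores: Sequence[float]) -> tuple[float, float]:
    """One-sided rank-sum test (Yes > No); returns (p_value, -log10 p).

    Small samples (both groups of size at most 8) use exact permutation
    enumeration (valid under ties); larger ones the normal approximation
    with tie and continuity corrections.
    """
    yes = np.asarray(yes_scores, dtype=float)
    no = np.asarray(no_scores, dtype=float)
    if yes.size == 0 or no.size == 0:
        raise ValueError("both score sets must be non-empty")
    pooled = np.concatenate([yes, no])
    if np.all(pooled == pooled[0]):
        return 1.0, 0.0
    if max(yes.size, no.size) <= EXACT_N:
        p = _exact_rank_sum_p(yes, no)
    else:
        _, p = stats.mannwhitneyu(yes, no, alternative="greater",
                                  method="asymptotic")
        p = float(p)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return p, -math.log10(p)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class _Genome:
    mask: np.ndarray       # (n_pwms,) bool, which motifs are members
    weights: np.ndarray    # (n_pwms,) float in [0, 1]
    max_counts: np.ndarray  # (n_pwms,) int in 1..3
    width: int

    def to_module(self, pwm_names: Sequence[str]) -> CompositeModule:
        members = tuple(
            ModuleMember(pwm_names[i], float(self.weights[i]),
                         int(self.max_counts[i]))
            for i in np.nonzero(self.mask)[0]
        )
        return CompositeModule(members, self.width)


def _random_genome(rng: np.random.Generator, n: int,
                   max_members: int) -> _Genome:
    k = int(rng.integers(1, min(max_members, n) + 1))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return _Genome(
        mask=mask,
        weights=rng.uniform(0.1, 1.0, size=n),
        max_counts=rng.integers(1, 4, size=n),
        width=int(rng.integers(W_MIN, W_MAX + 1)),
    )


def _repair(genome: _Genome, rng: np.random.Generator,
            max_members: int) -> None:
    k = int(genome.mask.sum())
    if k == 0:
        genome.mask[rng.integers(len(genome.mask))] = True
    elif k > max_members:
        on = np.nonzero(genome.mask)[0]
        off = rng.choice(on, size=k - max_members, replace=False)
        genome.mask[off] = False
    genome.width = int(np.clip(genome.width, W_MIN, W_MAX))


def _crossover(a: _Genome, b: _Genome, rng: np.random.Generator,
               p: float) -> _Genome:
    take_b = rng.random(len(a.mask)) < p
    child = _Genome(
        mask=np.where(take_b, b.mask, a.mask),
        weights=np.where(take_b, b.weights, a.weights),
        max_counts=np.where(take_b, b.max_counts, a.max_counts),
        width=b.width if rng.random() < p else a.width,
    )
    return child


def _mutate(genome: _Genome, rng: np.random.Generator, p: float) -> None:
    n = len(genome.mask)
    flip = rng.random(n) < p
    genome.mask[flip] = ~genome.mask[flip]
    jitter = rng.random(n) < p
    genome.weights[jitter] = np.clip(
        genome.weights[jitter] + rng.normal(0, 0.2, jitter.sum()), 0.0, 1.0)
    reroll = rng.random(n) < p
    genome.max_counts[reroll] = rng.integers(1, 4, int(reroll.sum()))
    if rng.random() < p:
        genome.width = int(np.clip(
            genome.width + rng.integers(-30, 31), W_MIN, W_MAX))


def optimize_module(enriched_pwms: Sequence[str],
                    yes_hit_index: HitIndex, yes_genes: Sequence[str],
                    no_hit_index: HitIndex, no_genes: Sequence[str],
                    ga_params: GaParams | None = None,
                    seed: int = 0,
                    promoter_length: int = 1100) -> CompositeModule:
    """Search for the module maximizing Yes/No rank-sum separation.

    Fully seeded and deterministic; elitism of 1 makes the best fitness
    non-decreasing across generations.
    """
    if not enriched_pwms:
        raise ValueError("need at least one enriched motif")
    params = ga_params or GaParams()
    params.validate()
    rng = np.random.default_rng(seed)
    pwm_names = list(enriched_pwms)
    n = len(pwm_names)

    cache: dict[tuple, tuple[float, float]] = {}

    def evaluate(genome: _Genome) -> tuple[float, float, float]:
        module = genome.to_module(pwm_names)
        key = (tuple(sorted(
            (m.pwm_name, round(m.weight, 6), m.max_count)
            for m in module.members)), module.window_width)
        if key not in cache:
            yes_s = score_set(yes_hit_index, yes_genes, module,
                              promoter_length)
            no_s = score_set(no_hit_index, no_genes, module, promoter_length)
            cache[key] = wilcoxon_fitness(yes_s, no_s)
        p, raw_fit = cache[key]
        fit = raw_fit - params.complexity_penalty * len(module.members)
        return fit, p, raw_fit

    population = [_random_genome(rng, n, params.max_members)
                  for _ in range(params.population)]
    scored = [evaluate(g) for g in population]

    for _ in range(params.generations):
        order = np.argsort([-s[0] for s in scored], kind="stable")
        elite = [population[i] for i in order[:params.elitism]]
        elite_scores = [scored[i] for i in order[:params.elitism]]
        children = []
        while len(children) < params.population - params.elitism:
            def pick() -> _Genome:
                idx = rng.integers(0, params.population,
                                   size=params.tournament_k)
                best = max(idx, key=lambda i: scored[i][0])
                return population[best]

            child = _crossover(pick(), pick(), rng, params.crossover_p)
            _mutate(child, rng, params.mutation_p)
            _repair(child, rng, params.max_members)
            children.append(child)
        population = elite + children
        scored = elite_scores + [evaluate(g) for g in children]

    best_i = max(range(len(population)), key=lambda i: scored[i][0])
    fit, p, raw_fit = scored[best_i]
    module = population[best_i].to_module(pwm_names)
    return replace(module, fitness=raw_fit, p_value=p)
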