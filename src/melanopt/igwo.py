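"""Gray Wolf Optimizer with an elite-archive improvement (IGWO).

Canonical GWO moves every wolf toward the three best solutions alpha, beta,
delta: per leader L,

    D = |2 r2 L - P|,   Xl = L - A D,   A = 2 a r1 - a,

with fresh uniforms r1, r2 per leader and dimension, and the new position
the mean of the three Xl, clamped to the box bounds. The control scalar
``a`` decays linearly from 2 to 0 over the run.

The improved variant keeps an archive S of elite solutions with selection
probabilities z_i = (1 - Fit(s_i)) / sum_j (1 - Fit(s_j)); each iteration
the first half of the population follows alpha/beta/delta while the second
half follows three archive members drawn by roulette wheel. Termination:
iteration budget T reached, best fitness exactly 0, or no strict
improvement of the best fitness for m consecutive iterations.

Genomes encode an MLP: gene 0 is the hidden-layer size H in [5, 30]; the
remaining genes are weights/biases in [-2, 2], of which the leading
H(X+1) + C(H+1) are active (fixed maximal-length encoding, unused genes
are inert).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np

__all__ = [
    "H_MIN",
    "H_MAX",
    "WEIGHT_MIN",
    "WEIGHT_MAX",
    "IGWOConfig",
    "Archive",
    "OptimizeResult",
    "genome_length",
    "genome_bounds",
    "decode_genome",
    "a_schedule",
    "leader_move",
    "update_archive",
    "roulette_select",
    "optimize",
]

H_MIN, H_MAX = 5, 30
WEIGHT_MIN, WEIGHT_MAX = -2.0, 2.0


@dataclass(frozen=True)
class IGWOConfig:
    """Optimizer run parameters.

    Defaults (population 250, T=300, m=100) are the full-scale settings;
    tests and the reduced pipeline pass smaller values.
    """

    population_size: int = 250
    max_iterations: int = 300
    stagnation_limit: int = 100
    seed: int = 0
    archive_capacity: int = 50
    mode: str = "igwo"

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.max_iterations < 1 or self.stagnation_limit < 1:
            raise ValueError("max_iterations and stagnation_limit must be >= 1")
        if self.mode not in ("igwo", "gwo"):
            raise ValueError("mode must be 'igwo' or 'gwo'")
        if self.archive_capacity < 0:
            raise ValueError("archive_capacity must be >= 0")


def genome_length(n_inputs: int, n_outputs: int, h_max: int = H_MAX) -> int:
    """1 size gene + the maximal weight-vector length H_max(X+1)+C(H_max+1)."""
    return 1 + h_max * (n_inputs + 1) + n_outputs * (h_max + 1)


def genome_bounds(n_inputs: int, n_outputs: int, h_max: int = H_MAX):
    """Per-gene (lower, upper) arrays for the box constraints."""
    dim = genome_length(n_inputs, n_outputs, h_max)
    lower = np.full(dim, WEIGHT_MIN)
    upper = np.full(dim, WEIGHT_MAX)
    lower[0], upper[0] = H_MIN, H_MAX
    return lower, upper


class NetworkSpec(NamedTuple):
    """Decoded MLP parameters."""

    n_hidden: int
    hidden_weights: np.ndarray  # (H, X)
    hidden_biases: np.ndarray  # (H,)
    output_weights: np.ndarray  # (C, H)
    output_biases: np.ndarray  # (C,)


def decode_genome(genome, n_inputs: int, n_outputs: int) -> NetworkSpec:
    """Read H from gene 0 (round half up, clipped to [5, 30]) and unpack the
    leading H(X+1)+C(H+1) weight genes in fixed order: hidden weights
    (row-major), hidden biases, output weights (row-major), output biases."""
    g = np.asarray(genome, dtype=float)
    h = int(np.clip(np.floor(g[0] + 0.5), H_MIN, H_MAX))
    idx = 1
    wh = g[idx: idx + h * n_inputs].reshape(h, n_inputs)
    idx += h * n_inputs
    bh = g[idx: idx + h]
    idx += h
    wo = g[idx: idx + n_outputs * h].reshape(n_outputs, h)
    idx += n_outputs * h
    bo = g[idx: idx + n_outputs]
    return NetworkSpec(h, wh, bh, wo, bo)


def a_schedule(t: int, max_iterations: int) -> float:
    """Linear decay a = 2 - 2t/G: a(0) = 2, a(G) = 0."""
    return 2.0 - 2.0 * t / max_iterations


def leader_move(position, leaders, a: float, rng, lower, upper) -> np.ndarray:
    """One encircling move guided by three leaders; result clamped to bounds.

    Draws r1, r2 as full-dimension uniform vectors per leader, in leader
    order — the RNG consumption contract every equivalence check relies on.
    """
    p = np.asarray(position, dtype=float)
    acc = np.zeros_like(p)
    for leader in leaders:
        r1 = rng.random(p.size)
        r2 = rng.random(p.size)
        big_a = 2.0 * a * r1 - a
        d = np.abs(2.0 * r2 * leader - p)
        acc += leader - big_a * d
    return np.clip(acc / len(leaders), lower, upper)


@dataclass
class Archive:
    """Elite solutions with roulette-selection probabilities.

    Members are unique up to ``tolerance`` (Euclidean); when the capacity is
    exceeded the worst-fitness member is evicted. ``probabilities`` is the
    normalized vector z_i = (1 - Fit_i) / sum(1 - Fit_j).
    """

    capacity: int = 50
    tolerance: float = 1e-9
    members: list = field(default_factory=list)  # (genome, fitness) pairs

    def __len__(self) -> int:
        return len(self.members)

    @property
    def fitnesses(self) -> np.ndarray:
        return np.array([f for _, f in self.members], dtype=float)

    @property
    def probabilities(self) -> np.ndarray:
        fits = self.fitnesses
        weights = 1.0 - fits
        total = weights.sum()
        if total <= 0:  # every member at the worst possible fitness
            return np.full(len(fits), 1.0 / len(fits))
        return weights / total


def update_archive(archive: Archive, candidates) -> Archive:
    """Insert each (genome, fitness) candidate that is new and better than
    the archive's mean fitness; evict the worst when over capacity."""
    for genome, fit in candidates:
        if archive.capacity == 0:
            break
        g = np.asarray(genome, dtype=float)
        if archive.members:
            dists = [np.linalg.norm(g - m) for m, _ in archive.members]
            if min(dists) <= archive.tolerance:
                continue
            if fit >= archive.fitnesses.mean():
                continue
        archive.members.append((g.copy(), float(fit)))
        if len(archive.members) > archive.capacity:
            worst = int(np.argmax(archive.fitnesses))
            archive.members.pop(worst)
    return archive


def roulette_select(archive: Archive, k: int, rng) -> np.ndarray:
    """Draw ``k`` member indices with replacement, proportionally to Z."""
    if len(archive) == 0:
        raise ValueError("cannot select from an empty archive")
    cum = np.cumsum(archive.probabilities)
    cum[-1] = 1.0
    draws = rng.random(k)
    return np.searchsorted(cum, draws, side="right").clip(0, len(archive) - 1)


class OptimizeResult(NamedTuple):
    best_genome: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness per iteration
    n_iterations: int
    termination: str  # 'max_iterations' | 'zero_fitness' | 'stagnation'


def optimize(fitness_fn: Callable, config: IGWOConfig, bounds) -> OptimizeResult:
    """Run the (I)GWO loop on a fitness in [0, 1] (lower is better).

    ``bounds`` is a (lower, upper) pair of per-gene arrays. In ``igwo`` mode
    the second half of the population (indices >= ceil(n/2)) follows three
    roulette-selected archive members, falling back to the alpha/beta/delta
    leaders while the archive is empty; ``gwo`` mode disables the archive
    entirely. All randomness flows from one generator seeded by config.seed.
    """
    lower, upper = (np.asarray(b, dtype=float) for b in bounds)
    dim = lower.size
    n = config.population_size
    rng = np.random.default_rng(config.seed)
    pop = rng.uniform(lower, upper, size=(n, dim))
    archive = Archive(capacity=config.archive_capacity)
    half = (n + 1) // 2  # first `half` wolves follow the leaders
    best_genome = None
    best_fit = np.inf
    stagnation = 0
    history = []
    termination = "max_iterations"
    t = 0
    while t < config.max_iterations:
        t += 1
        fits = np.array([float(fitness_fn(p)) for p in pop])
        if np.any((fits < 0) | (fits > 1)):
            raise ValueError("fitness_fn must return values in [0, 1]")
        order = np.argsort(fits, kind="stable")
        leaders = [pop[order[j]].copy() for j in range(3)]
        if fits[order[0]] < best_fit:
            best_fit = float(fits[order[0]])
            best_genome = pop[order[0]].copy()
            stagnation = 0
        else:
            stagnation += 1
        history.append(best_fit)
        if config.mode == "igwo":
            update_archive(archive, [(pop[order[j]], fits[order[j]]) for j in range(3)])
        if best_fit == 0.0:
            termination = "zero_fitness"
            break
        if stagnation >= config.stagnation_limit:
            termination = "stagnation"
            break
        if t == config.max_iterations:
            termination = "max_iterations"
            break
        a = a_schedule(t, config.max_iterations)
        for i in range(n):
            if config.mode == "igwo" and i >= half and len(archive) > 0:
                idx = roulette_select(archive, 3, rng)
                guides = [archive.members[j][0] for j in idx]
            else:
                guides = leaders
            pop[i] = leader_move(pop[i], guides, a, rng, lower, upper)
    return OptimizeResult(
        best_genome=best_genome,
        best_fitness=best_fit,
        history=np.asarray(history),
        n_iterations=t,
        termination=termination,
    )
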