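"""Inclusive-fitness payoffs, roulette-wheel selection and generation turnover.

A delivered food item is worth ``c`` to the robot that keeps it, or a
total of ``b`` split equally (b/7 each) among its seven group-mates when
shared.  Only the ratio c/b matters for the direction of selection, so
payoffs are normalized to b = 1, c = ratio.

An individual's inclusive fitness over an evaluation is

    f_i = c * n_selfish_i + (b / (n - 1)) * sum_{j != i in group} n_shared_j

Reproductive competition is population-wide: founders of the next
generation are drawn by roulette-wheel selection (with replacement)
across all m*n individuals, paired for single-point crossover, mutated
per bit, then cloned into groups according to the composition scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import genome as _g
from .relatedness import GroupComposition, compose_groups

DEFAULT_MUTATION_RATE = 0.005   # per bit
DEFAULT_CROSSOVER_RATE = 0.005  # per founder pair


@dataclass(frozen=True)
class PayoffScheme:
    c: float
    b: float

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("benefit b must be positive")
        if self.c < 0:
            raise ValueError("cost c must be nonnegative")

    @property
    def ratio(self) -> float:
        return self.c / self.b


@dataclass(frozen=True)
class AltruismLevel:
    """A = n_a / (n_a + n_s); undefined when no items were collected."""

    n_a: int
    n_s: int

    @property
    def defined(self) -> bool:
        return self.n_a + self.n_s > 0

    @property
    def A(self) -> float:
        if not self.defined:
            return float("nan")
        return self.n_a / (self.n_a + self.n_s)


def make_payoff(ratio: float) -> PayoffScheme:
    """Payoff scheme with b = 1 and c = ratio (only c/b matters)."""
    if ratio < 0:
        raise ValueError("c/b ratio must be nonnegative")
    return PayoffScheme(c=float(ratio), b=1.0)


def inclusive_fitness(n_selfish: np.ndarray, n_shared: np.ndarray,
                      scheme: PayoffScheme) -> np.ndarray:
    """Per-robot inclusive fitness from group delivery counts.

    Accepts (..., n) arrays with the trailing axis indexing robots in a
    group; broadcasts over any leading group axes.
    """
    ns = np.asarray(n_selfish, dtype=float)
    na = np.asarray(n_shared, dtype=float)
    if ns.shape != na.shape:
        raise ValueError("selfish and shared count arrays must have the same shape")
    if (ns < 0).any() or (na < 0).any():
        raise ValueError("delivery counts must be nonnegative")
    n = ns.shape[-1]
    others_shared = na.sum(axis=-1, keepdims=True) - na
    return scheme.c * ns + (scheme.b / (n - 1)) * others_shared


def roulette_select(fitnesses: np.ndarray, n_draws: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Fitness-proportional sampling with replacement: P(i) = f_i / sum f.

    If every fitness is zero (possible early on at very small c/b with
    unrelated groups), falls back to uniform random selection instead of
    letting the population go extinct.
    """
    f = np.asarray(fitnesses, dtype=float)
    if (f < 0).any():
        raise ValueError("fitnesses must be nonnegative")
    total = f.sum()
    if total <= 0:
        return rng.integers(0, f.size, size=n_draws)
    cum = np.cumsum(f) / total
    return np.searchsorted(cum, rng.random(n_draws), side="right").clip(0, f.size - 1)


def _vary_founders(founder_genes: np.ndarray, crossover_rate: float,
                   mutation_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Pair founders sequentially for crossover, then mutate per bit."""
    genes = founder_genes.copy()
    n = genes.shape[0]
    if crossover_rate > 0 and n >= 2:
        n_pairs = n // 2
        do = rng.random(n_pairs) < crossover_rate
        cuts = rng.integers(1, _g.N_BITS, size=n_pairs)
        for p in np.nonzero(do)[0]:
            a, b = 2 * p, 2 * p + 1
            ga, gb = _g.crossover_at(_g.Genome(genes[a]), _g.Genome(genes[b]), int(cuts[p]))
            genes[a], genes[b] = ga.genes, gb.genes
    if mutation_rate > 0:
        genes = _g.mutate_genes(genes, mutation_rate, rng)
    return genes


def next_generation(group_genomes: np.ndarray, fitnesses: np.ndarray,
                    scheme: GroupComposition, rng: np.random.Generator,
                    mutation_rate: float = DEFAULT_MUTATION_RATE,
                    crossover_rate: float = DEFAULT_CROSSOVER_RATE) -> np.ndarray:
    """One full reproduction cycle; returns the next (m, n, 33) population.

    Selection is population-wide roulette over all m*n individuals.  The
    number of founders drawn equals the number of clone-type slots
    (m * n_types); each founder is then cloned to its type's copy number
    inside its group, so within-group relatedness is re-established
    every generation.
    """
    genomes = np.asarray(group_genomes, dtype=np.uint8)
    m, n = genomes.shape[:2]
    if (m, n) != (scheme.m, scheme.n):
        raise ValueError("population shape does not match the composition scheme")
    f = np.asarray(fitnesses, dtype=float).reshape(m * n)
    flat = genomes.reshape(m * n, -1)
    n_founders = scheme.m * scheme.n_types
    idx = roulette_select(f, n_founders, rng)
    founders = _vary_founders(flat[idx], crossover_rate, mutation_rate, rng)
    return compose_groups(founders, scheme, rng)


def altruism_of_group(n_a: int, n_s: int) -> AltruismLevel:
    """Share fraction A = n_a / (n_a + n_s) for one group."""
    if n_a < 0 or n_s < 0:
        raise ValueError("counts must be nonnegative")
    return AltruismLevel(n_a=int(n_a), n_s=int(n_s))


def population_altruism(shared_counts: np.ndarray, selfish_counts: np.ndarray) -> float:
    """Mean A over groups that collected at least one item (NaN if none).

    ``shared_counts``/``selfish_counts`` are (m, n) per-robot totals.
    """
    na = np.asarray(shared_counts).sum(axis=-1).astype(float)
    ns = np.asarray(selfish_counts).sum(axis=-1).astype(float)
    tot = na + ns
    defined = tot > 0
    if not defined.any():
        return float("nan")
    return float((na[defined] / tot[defined]).mean())
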