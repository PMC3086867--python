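"""Group composition, regression relatedness and the drift statistic.

Within-group relatedness is manipulated by cloning founder genomes:
each group of n individuals is built from k clone types with copy
numbers (k_1, ..., k_k) summing to n.  Because founders are drawn at
random from the population, they are treated as genetically distinct,
so genetic identity arises only through cloning.

Under the regression definition, relatedness compares the probability
that a random social partner of a focal individual is its clone within
the group (p_group) against the same probability for a random partner
drawn from the whole population (p_pop):

    r = (p_group - p_pop) / (1 - p_pop)

with self-pairs excluded from both probabilities.  For m groups of n:

    p_group = sum_i (k_i / n) * (k_i - 1) / (n - 1)
    p_pop   = m * sum_i k_i (k_i - 1) / (N (N - 1)),   N = m n

A clonal scheme {8} gives r = 1 exactly; fully random grouping {1x8}
gives r = 0; the two-type 1:7 scheme at m = 200 gives r = 0.7492.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

#: named relatedness levels -> clone copy-number schemes for groups of 8
SCHEME_VOCABULARY = {
    "r0": (1, 1, 1, 1, 1, 1, 1, 1),
    "r25": (3, 3, 2),
    "r50": (6, 1, 1),
    "r75": (7, 1),
    "r100": (8,),
}


@dataclass(frozen=True)
class GroupComposition:
    """Clone copy numbers within a group, plus population dimensions."""

    clone_counts: tuple
    m: int = 200  # number of groups

    def __post_init__(self):
        counts = tuple(int(k) for k in self.clone_counts)
        if any(k < 1 for k in counts):
            raise ValueError("clone counts must be positive integers")
        object.__setattr__(self, "clone_counts", counts)
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.m < 1:
            raise ValueError("need at least one group")

    @property
    def n(self) -> int:
        return sum(self.clone_counts)

    @property
    def n_types(self) -> int:
        return len(self.clone_counts)

    @property
    def population_size(self) -> int:
        return self.m * self.n

    @classmethod
    def from_name(cls, name: str, m: int = 200) -> "GroupComposition":
        if name not in SCHEME_VOCABULARY:
            raise ValueError(f"unknown scheme {name!r}; known: {sorted(SCHEME_VOCABULARY)}")
        return cls(SCHEME_VOCABULARY[name], m=m)


@dataclass(frozen=True)
class RelatednessReport:
    r_analytic: float
    p_group: float
    p_pop: float


@dataclass(frozen=True)
class DriftVariance:
    """Standardized variance F = Var(p) / (p_bar q_bar) across replicates."""

    F: float
    p_values: np.ndarray
    p_bar: float
    defined: bool

    @property
    def q_bar(self) -> float:
        return 1.0 - self.p_bar


def regression_relatedness(scheme: GroupComposition) -> RelatednessReport:
    """Analytic regression relatedness for a clone-composition scheme.

    Computed in exact rational arithmetic and returned as floats, so the
    result agrees with brute-force pair enumeration to machine precision.
    """
    n, m = scheme.n, scheme.m
    N = scheme.population_size
    pairs = sum(k * (k - 1) for k in scheme.clone_counts)
    p_group = Fraction(pairs, n * (n - 1))
    p_pop = Fraction(m * pairs, N * (N - 1))
    r = (p_group - p_pop) / (1 - p_pop)
    return RelatednessReport(r_analytic=float(r), p_group=float(p_group),
                             p_pop=float(p_pop))


def relatedness_by_enumeration(scheme: GroupComposition) -> float:
    """Brute-force oracle: identity probabilities over all ordered pairs.

    Builds the explicit population of m*n individuals labelled by founder
    identity and averages clone-identity over every ordered within-group
    pair (p_group) and every ordered pair in the population (p_pop).
    Intended for small populations; scales as (m n)^2.
    """
    labels = []
    groups = []
    t = 0
    for g in range(scheme.m):
        for k in scheme.clone_counts:
            labels.extend([t] * k)
            groups.extend([g] * k)
            t += 1
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    same_label = labels[:, None] == labels[None, :]
    same_group = groups[:, None] == groups[None, :]
    off_diag = ~np.eye(labels.size, dtype=bool)
    p_group = same_label[same_group & off_diag].mean()
    p_pop = same_label[off_diag].mean()
    return float((p_group - p_pop) / (1.0 - p_pop))


def compose_groups(founders: np.ndarray, scheme: GroupComposition,
                   rng: np.random.Generator) -> np.ndarray:
    """Clone founder genomes into groups: (m, n, 33) uint8.

    ``founders`` must supply m * n_types genomes for cloned schemes (one
    per clone type per group); the all-distinct scheme consumes m * n.
    Founder-to-group assignment and positions within each group are
    randomized.
    """
    founders = np.asarray(founders, dtype=np.uint8)
    needed = scheme.m * scheme.n_types
    if founders.shape[0] < needed:
        raise ValueError(f"scheme needs {needed} founders, got {founders.shape[0]}")
    order = rng.permutation(needed)
    by_group = founders[order].reshape(scheme.m, scheme.n_types, -1)
    rep = np.repeat(np.arange(scheme.n_types), scheme.clone_counts)
    groups = by_group[:, rep, :]  # (m, n, 33)
    # shuffle robot positions independently within each group
    perm = np.argsort(rng.random((scheme.m, scheme.n)), axis=1)
    return np.take_along_axis(groups, perm[:, :, None], axis=1)


def queller_goodnight_estimate(genotypes: np.ndarray, group_labels: np.ndarray) -> float:
    """Empirical regression relatedness from genotype bit matrices.

    ``genotypes`` is an (N, L) 0/1 matrix (one row per individual, one
    column per biallelic locus) and ``group_labels`` assigns each row to
    a group.  The estimator regresses the partner's allelic state on the
    focal's over all ordered within-group pairs, centring both by the
    population allele frequencies and pooling numerator and denominator
    over loci and pairs:

        r_hat = sum_pairs sum_l (x_partner,l - p_l)(x_focal,l - p_l)
              / sum_pairs sum_l (x_focal,l - p_l)^2

    For clonal groups r_hat = 1; for random grouping it converges to
    roughly -1/(N-1); it converges to the analytic regression value as
    the locus count grows.  Returns NaN for populations monomorphic at
    every locus (the regression is undefined).
    """
    x = np.asarray(genotypes, dtype=float)
    labels = np.asarray(group_labels)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("genotypes must be a 2-D (individuals x loci) matrix")
    if labels.shape[0] != x.shape[0]:
        raise ValueError("one group label per individual is required")
    if np.unique(labels).size < 2:
        raise ValueError("need at least two groups")
    p = x.mean(axis=0)
    if np.all((p == 0) | (p == 1)):
        return float("nan")
    xc = x - p
    num = 0.0
    den = 0.0
    for g in np.unique(labels):
        xg = xc[labels == g]
        ng = xg.shape[0]
        if ng < 2:
            continue
        s = xg.sum(axis=0)
        # sum over ordered pairs (focal j, partner l != j) of xc_l * xc_j
        num += float((xg * (s - xg)).sum())
        den += float((ng - 1) * (xg ** 2).sum())
    if den == 0.0:
        return float("nan")
    return num / den


def standardized_variance(p_values) -> DriftVariance:
    """Drift statistic F = Var(p) / (p_bar (1 - p_bar)) across replicates.

    Uses the sample variance (divisor n-1).  Undefined (``defined`` is
    False and F is NaN) when the mean proportion is exactly 0 or 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two replicate proportions")
    p_bar = float(p.mean())
    if p_bar <= 0.0 or p_bar >= 1.0:
        return DriftVariance(F=float("nan"), p_values=p, p_bar=p_bar, defined=False)
    F = float(p.var(ddof=1) / (p_bar * (1.0 - p_bar)))
    return DriftVariance(F=F, p_values=p, p_bar=p_bar, defined=True)
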