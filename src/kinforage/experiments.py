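"""Evolution driver, mutation-effect screens and summary statistics.

``run_evolution`` evolves one population (m groups of n robots) for a
number of generations: evaluate every group in seeded foraging trials,
assign inclusive fitness, then produce the next generation by roulette
selection, crossover, mutation and clone-composition.  Many populations
can be evolved in lockstep (``run_evolution_batch``), which vectorizes
arena simulation across every group, trial and population at once; a
treatment grid (``run_sweep``) is a single such batch.

Three screens probe the genotype-phenotype map of evolved controllers
with the medium-effect point mutation (third-bit flip, +/-32):

* ``pleiotropy_screen`` asks whether one mutation significantly changes
  foraging performance, altruism, or both (rank-sum tests);
* ``epistasis_screen`` asks whether the fitness effect of a second
  mutation B depends on the presence of a first mutation A, via a
  contrast-of-differences z score over four conditions
  F(0), F(A), F(B), F(AB);
* ``weak_selection_screen`` measures how often a single mutation moves
  the 100-trial mean performance or altruism by more than 25%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .arena import ArenaConfig, genomes_to_arrays, simulate_worlds
from .genome import N_GENES, THIRD_BIT_VALUE, random_population
from .relatedness import (
    GroupComposition,
    compose_groups,
    regression_relatedness,
    standardized_variance,
)
from .selection import (
    DEFAULT_CROSSOVER_RATE,
    DEFAULT_MUTATION_RATE,
    PayoffScheme,
    inclusive_fitness,
    make_payoff,
    next_generation,
    population_altruism,
)

#: default c/b treatment levels; chosen so the r = c/b diagonal exists
#: against the analytic relatedness levels of the five clone schemes
DEFAULT_RATIOS = (0.01, 0.2468, 0.5357, 0.7492, 1.0)


@dataclass
class EvolutionLog:
    """Per-generation record of one evolving population."""

    scheme: GroupComposition
    ratio: float
    seed: int
    table: pd.DataFrame  # columns: generation, mean_items_per_trial, mean_altruism
    final_population: np.ndarray  # (m, n, 33) uint8, after the last evaluated generation

    @property
    def r_analytic(self) -> float:
        return regression_relatedness(self.scheme).r_analytic

    def final_mean(self, column: str, window: int = 10) -> float:
        """Mean of a logged column over the last ``window`` generations."""
        tail = self.table[column].tail(window)
        return float(tail.mean())


def hamilton_threshold(r: float, ratio: float) -> str:
    """Predicted direction of selection from the sign of r - c/b."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("relatedness must lie in [0, 1]")
    if ratio < 0:
        raise ValueError("c/b ratio must be nonnegative")
    if r > ratio:
        return "altruism-favored"
    if r < ratio:
        return "selfish-favored"
    return "neutral"


def _evaluate_populations(pops: np.ndarray, cfg: ArenaConfig, trials: int,
                          rng: np.random.Generator, weight_range: float):
    """Evaluate every group of every population: (P, m, n) count totals."""
    P, m, n = pops.shape[:3]
    w_in, w_out = genomes_to_arrays(pops.reshape(P * m, n, -1), weight_range)
    w_in_b = np.repeat(w_in, trials, axis=0)
    w_out_b = np.repeat(w_out, trials, axis=0)
    selfish, shared = simulate_worlds(w_in_b, w_out_b, cfg, rng)
    selfish = selfish.reshape(P, m, trials, n).sum(axis=2)
    shared = shared.reshape(P, m, trials, n).sum(axis=2)
    return selfish, shared


def initial_population(scheme: GroupComposition, rng: np.random.Generator) -> np.ndarray:
    """Generation-0 population: uniform-random founders, clone-composed."""
    founders = random_population(scheme.m * scheme.n_types, rng)
    return compose_groups(founders, scheme, rng)


def run_evolution_batch(schemes, ratios, generations: int, seed: int,
                        cfg: ArenaConfig | None = None, trials: int = 10,
                        weight_range: float = 1.0,
                        mutation_rate: float = DEFAULT_MUTATION_RATE,
                        crossover_rate: float = DEFAULT_CROSSOVER_RATE,
                        initial_populations=None) -> list[EvolutionLog]:
    """Evolve several independent populations in lockstep.

    ``schemes`` and ``ratios`` are parallel lists defining one population
    each.  Populations are statistically independent (each has its own
    RNG stream) but are evaluated in one arena batch per generation.
    ``initial_populations`` (a (P, m, n, 33) array or list of (m, n, 33)
    arrays) replaces the default uniform-random generation 0, e.g. to
    resume a run from serialized genomes.
    """
    cfg = cfg or ArenaConfig()
    schemes = list(schemes)
    ratios = [float(x) for x in ratios]
    if len(schemes) != len(ratios):
        raise ValueError("schemes and ratios must have the same length")
    P = len(schemes)
    if generations < 1:
        raise ValueError("need at least one generation")
    if len({(s.m, s.n) for s in schemes}) != 1:
        raise ValueError("all populations in one batch must share m and n")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(P + 1)
    arena_rng = np.random.default_rng(children[0])
    pop_rngs = [np.random.default_rng(c) for c in children[1:]]
    payoffs = [make_payoff(x) for x in ratios]

    if initial_populations is None:
        pops = np.stack([initial_population(s, r) for s, r in zip(schemes, pop_rngs)])
    else:
        pops = np.stack([np.asarray(p, dtype=np.uint8) for p in initial_populations])
        if pops.shape != (P, schemes[0].m, schemes[0].n, 33):
            raise ValueError("initial populations do not match the schemes' shape")
    records: list[list] = [[] for _ in range(P)]
    for gen in range(generations):
        selfish, shared = _evaluate_populations(pops, cfg, trials, arena_rng, weight_range)
        new_pops = np.empty_like(pops)
        for p in range(P):
            total = selfish[p].sum() + shared[p].sum()
            records[p].append((gen, total / (schemes[p].m * trials),
                               population_altruism(shared[p], selfish[p])))
            f = inclusive_fitness(selfish[p], shared[p], payoffs[p])
            new_pops[p] = next_generation(pops[p], f, schemes[p], pop_rngs[p],
                                          mutation_rate=mutation_rate,
                                          crossover_rate=crossover_rate)
        final = pops.copy() if gen == generations - 1 else None
        if gen < generations - 1:
            pops = new_pops
    logs = []
    for p in range(P):
        table = pd.DataFrame(records[p],
                             columns=["generation", "mean_items_per_trial", "mean_altruism"])
        logs.append(EvolutionLog(scheme=schemes[p], ratio=ratios[p], seed=seed,
                                 table=table, final_population=final[p]))
    return logs


def run_evolution(scheme: GroupComposition, ratio: float, generations: int,
                  seed: int, cfg: ArenaConfig | None = None, trials: int = 10,
                  weight_range: float = 1.0,
                  mutation_rate: float = DEFAULT_MUTATION_RATE,
                  crossover_rate: float = DEFAULT_CROSSOVER_RATE,
                  initial_population=None) -> EvolutionLog:
    """Evolve a single population; fully reproducible from ``seed``."""
    init = None if initial_population is None else [initial_population]
    return run_evolution_batch([scheme], [ratio], generations, seed, cfg=cfg,
                               trials=trials, weight_range=weight_range,
                               mutation_rate=mutation_rate,
                               crossover_rate=crossover_rate,
                               initial_populations=init)[0]


def run_sweep(scheme_names, ratios, m: int, generations: int, n_seeds: int,
              seed: int, cfg: ArenaConfig | None = None, trials: int = 10,
              **kwargs) -> pd.DataFrame:
    """Run a relatedness x c/b treatment grid with replicate populations.

    Returns one row per (scheme, ratio, replicate) with the analytic r,
    the final mean altruism and final foraging efficiency (each averaged
    over the last 10 generations), and the diagonal flag (treatments are
    labelled diagonal when the scheme's index in ``scheme_names`` equals
    the ratio's index in ``ratios``, matching the treatment design where
    each relatedness level is paired with its own c/b value).
    """
    scheme_names = list(scheme_names)
    ratios = [float(x) for x in ratios]
    cells = [(si, ri) for si in range(len(scheme_names)) for ri in range(len(ratios))]
    schemes, cell_ratios, meta = [], [], []
    for rep in range(n_seeds):
        for si, ri in cells:
            schemes.append(GroupComposition.from_name(scheme_names[si], m=m))
            cell_ratios.append(ratios[ri])
            meta.append((scheme_names[si], si, ri, rep))
    logs = run_evolution_batch(schemes, cell_ratios, generations, seed,
                               cfg=cfg, trials=trials, **kwargs)
    rows = []
    for (name, si, ri, rep), log in zip(meta, logs):
        sign = np.sign(si - ri)
        rows.append({
            "scheme": name, "ratio": log.ratio, "replicate": rep,
            "r": log.r_analytic,
            "final_altruism": log.final_mean("mean_altruism"),
            "final_items": log.final_mean("mean_items_per_trial"),
            "cell_class": {-1: "below", 0: "diagonal", 1: "above"}[int(sign)],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Mutation-effect screens
# ---------------------------------------------------------------------

@dataclass
class MutationScreenResult:
    """Per-individual outcome of the single-mutation (pleiotropy) screen."""

    table: pd.DataFrame
    perf_pre: np.ndarray   # (k, trials) focal items per trial, before mutation
    perf_post: np.ndarray
    alt_pre: np.ndarray    # (k, trials) focal share fraction, NaN where no items
    alt_post: np.ndarray

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())

    def class_counts(self) -> dict:
        t = self.table[~self.table["excluded"]]
        return {c: int((t["classification"] == c).sum())
                for c in ("performance-only", "altruism-only", "both", "neither")}


@dataclass
class EpistasisResult:
    """Per-individual contrast-of-differences z over four mutation states."""

    table: pd.DataFrame  # mean/sd for F(0), F(A), F(B), F(AB), z, significant


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value, robust to degenerate samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def _focal_samples(groups: np.ndarray, focal: np.ndarray, cfg: ArenaConfig,
                   trials: int, rng: np.random.Generator, weight_range: float,
                   payoff: PayoffScheme | None = None):
    """Per-trial focal performance/altruism (and fitness) for k groups.

    ``groups`` is (k, n, 33); ``focal`` gives the focal robot index in
    each group.  Returns (performance, altruism[, fitness]) arrays of
    shape (k, trials); altruism is NaN for trials where the focal
    collected nothing.
    """
    k, n = groups.shape[:2]
    w_in, w_out = genomes_to_arrays(groups, weight_range)
    w_in_b = np.repeat(w_in, trials, axis=0)
    w_out_b = np.repeat(w_out, trials, axis=0)
    selfish, shared = simulate_worlds(w_in_b, w_out_b, cfg, rng)
    selfish = selfish.reshape(k, trials, n)
    shared = shared.reshape(k, trials, n)
    fs = np.take_along_axis(selfish, focal[:, None, None], axis=2)[:, :, 0]
    fa = np.take_along_axis(shared, focal[:, None, None], axis=2)[:, :, 0]
    perf = (fs + fa).astype(float)
    with np.errstate(invalid="ignore"):
        alt = np.where(perf > 0, fa / np.maximum(perf, 1), np.nan)
    if payoff is None:
        return perf, alt
    fit = inclusive_fitness(selfish, shared, payoff)
    fit_focal = np.take_along_axis(fit, focal[:, None, None], axis=2)[:, :, 0]
    return perf, alt, fit_focal


def pleiotropy_screen(population: np.ndarray, rng: np.random.Generator,
                      n_individuals: int | None = None, trials: int = 100,
                      alpha: float = 0.05, cfg: ArenaConfig | None = None,
                      weight_range: float = 1.0,
                      gene_indices: np.ndarray | None = None) -> MutationScreenResult:
    """Single-mutation screen for pleiotropic effects.

    For one randomly chosen individual per sampled group, flip the third
    bit of a random gene (mutation size +/-32), evaluate the individual
    embedded in its own group for ``trials`` seeded trials before and
    after, and rank-sum test performance (items collected by the focal)
    and altruism (share fraction of those items).  Individuals that
    collect no item in any trial either before or after are excluded,
    since their altruism is undefined throughout.
    """
    cfg = cfg or ArenaConfig()
    pop = np.asarray(population, dtype=np.uint8)
    m, n = pop.shape[:2]
    k = m if n_individuals is None else min(n_individuals, m)
    group_idx = rng.choice(m, size=k, replace=False)
    focal = rng.integers(0, n, size=k)
    genes = (rng.integers(0, N_GENES, size=k) if gene_indices is None
             else np.asarray(gene_indices))
    groups_pre = pop[group_idx].copy()
    groups_post = groups_pre.copy()
    groups_post[np.arange(k), focal, genes] ^= THIRD_BIT_VALUE

    layout_seed = rng.integers(0, 2**31)
    perf_pre, alt_pre = _focal_samples(groups_pre, focal, cfg, trials,
                                       np.random.default_rng(layout_seed), weight_range)
    perf_post, alt_post = _focal_samples(groups_post, focal, cfg, trials,
                                         np.random.default_rng(layout_seed), weight_range)

    rows = []
    for i in range(k):
        excluded = perf_pre[i].sum() == 0 and perf_post[i].sum() == 0
        p_perf = _ranksum_p(perf_pre[i], perf_post[i])
        p_alt = _ranksum_p(alt_pre[i], alt_post[i])
        sig_perf = bool(p_perf < alpha) if np.isfinite(p_perf) else False
        sig_alt = bool(p_alt < alpha) if np.isfinite(p_alt) else False
        cls = {(True, True): "both", (True, False): "performance-only",
               (False, True): "altruism-only", (False, False): "neither"}[(sig_perf, sig_alt)]
        rows.append({
            "group": int(group_idx[i]), "robot": int(focal[i]), "gene": int(genes[i]),
            "perf_pre_mean": float(perf_pre[i].mean()),
            "perf_post_mean": float(perf_post[i].mean()),
            "alt_pre_mean": float(np.nanmean(alt_pre[i])) if np.isfinite(alt_pre[i]).any() else float("nan"),
            "alt_post_mean": float(np.nanmean(alt_post[i])) if np.isfinite(alt_post[i]).any() else float("nan"),
            "p_performance": p_perf, "p_altruism": p_alt,
            "sig_performance": sig_perf, "sig_altruism": sig_alt,
            "classification": cls, "excluded": bool(excluded),
        })
    return MutationScreenResult(table=pd.DataFrame(rows), perf_pre=perf_pre,
                                perf_post=perf_post, alt_pre=alt_pre, alt_post=alt_post)


def epistasis_z(means: np.ndarray, sds: np.ndarray, trials: int) -> float:
    """Contrast-of-differences z from condition (F0, FA, FB, FAB) stats.

    z = [(mean FAB - mean FB) - (mean FA - mean F0)]
        / sqrt((s2_AB + s2_B + s2_A + s2_0) / trials)

    NaN when every condition has zero variance (contrast undefined).
    """
    m0, ma, mb, mab = means
    s2 = float(np.sum(np.square(sds)))
    if s2 == 0.0:
        return float("nan")
    return float(((mab - mb) - (ma - m0)) / np.sqrt(s2 / trials))


def epistasis_screen(population: np.ndarray, payoff: PayoffScheme,
                     rng: np.random.Generator, n_individuals: int | None = None,
                     trials: int = 100, z_crit: float = 2.0,
                     cfg: ArenaConfig | None = None,
                     weight_range: float = 1.0) -> EpistasisResult:
    """Two-mutation screen for epistasis on inclusive fitness.

    For each sampled individual, build the four genotypes {0, A, B, AB}
    from two medium-effect mutations at distinct random genes, evaluate
    each for ``trials`` trials in the individual's own group, and test
    whether mutation B has the same fitness effect with and without A
    (|z| > ``z_crit``).  Individuals collecting no item in any condition
    are excluded.
    """
    cfg = cfg or ArenaConfig()
    pop = np.asarray(population, dtype=np.uint8)
    m, n = pop.shape[:2]
    k = m if n_individuals is None else min(n_individuals, m)
    group_idx = rng.choice(m, size=k, replace=False)
    focal = rng.integers(0, n, size=k)
    gene_a = rng.integers(0, N_GENES, size=k)
    # B hits a different locus than A, so AB never collapses back to 0
    gene_b = (gene_a + rng.integers(1, N_GENES, size=k)) % N_GENES

    conds = []
    for with_a, with_b in ((0, 0), (1, 0), (0, 1), (1, 1)):
        g = pop[group_idx].copy()
        if with_a:
            g[np.arange(k), focal, gene_a] ^= THIRD_BIT_VALUE
        if with_b:
            g[np.arange(k), focal, gene_b] ^= THIRD_BIT_VALUE
        conds.append(g)

    layout_seed = rng.integers(0, 2**31)
    perf = np.empty((4, k, trials))
    fit = np.empty((4, k, trials))
    for ci, g in enumerate(conds):
        p, _, f = _focal_samples(g, focal, cfg, trials,
                                 np.random.default_rng(layout_seed),
                                 weight_range, payoff=payoff)
        perf[ci], fit[ci] = p, f

    rows = []
    for i in range(k):
        means = fit[:, i].mean(axis=1)
        sds = fit[:, i].std(axis=1, ddof=1)
        excluded = perf[:, i].sum() == 0
        z = epistasis_z(means, sds, trials)
        rows.append({
            "group": int(group_idx[i]), "robot": int(focal[i]),
            "gene_a": int(gene_a[i]), "gene_b": int(gene_b[i]),
            "mean_F0": means[0], "mean_FA": means[1],
            "mean_FB": means[2], "mean_FAB": means[3],
            "sd_F0": sds[0], "sd_FA": sds[1], "sd_FB": sds[2], "sd_FAB": sds[3],
            "z": z,
            "significant": bool(np.isfinite(z) and abs(z) > z_crit),
            "flagged": bool(not np.isfinite(z)),
            "excluded": bool(excluded),
        })
    return EpistasisResult(table=pd.DataFrame(rows))


def weak_selection_screen(screen: MutationScreenResult,
                          threshold: float = 0.25) -> dict:
    """Fractions of mutations changing trait means by more than 25%.

    Relative change is |post - pre| / pre on the per-individual trial
    means; a pre-mutation mean of zero counts as a large change exactly
    when the post-mutation mean is positive.  Excluded individuals are
    not counted.  Returns fractions and counts for performance and for
    altruism (altruism restricted to individuals with a defined pre and
    post mean).
    """
    t = screen.table[~screen.table["excluded"]]

    def frac(pre, post):
        pre = pre.to_numpy(float)
        post = post.to_numpy(float)
        ok = np.isfinite(pre) & np.isfinite(post)
        pre, post = pre[ok], post[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(post - pre) / pre
        large = np.where(pre > 0, rel > threshold, post > 0)
        return float(large.mean()) if large.size else float("nan"), int(large.sum()), int(large.size)

    f_perf, n_perf, tot_perf = frac(t["perf_pre_mean"], t["perf_post_mean"])
    f_alt, n_alt, tot_alt = frac(t["alt_pre_mean"], t["alt_post_mean"])
    return {
        "performance_fraction": f_perf, "performance_count": n_perf,
        "performance_total": tot_perf,
        "altruism_fraction": f_alt, "altruism_count": n_alt,
        "altruism_total": tot_alt,
    }


# ---------------------------------------------------------------------
# Treatment-grid statistics
# ---------------------------------------------------------------------

def results_statistics(sweep: pd.DataFrame) -> dict:
    """Summary statistics over a treatment grid of replicate populations.

    Expects the ``run_sweep`` output (or an equivalently shaped table).
    Returns per-treatment means, one-sample Wilcoxon tests of diagonal
    altruism against 0.5, the drift statistic F per treatment cell with
    a class comparison (diagonal vs off-diagonal, Mann-Whitney), and
    Pearson correlations of final altruism with r - c/b on each sign
    branch.
    """
    df = sweep.dropna(subset=["final_altruism"]).copy()
    df["r_minus_ratio"] = df["r"] - df["ratio"]
    cell = (df.groupby(["scheme", "ratio", "cell_class"], as_index=False)
              .agg(mean_altruism=("final_altruism", "mean"),
                   median_altruism=("final_altruism", "median"),
                   mean_items=("final_items", "mean"),
                   r=("r", "first"),
                   n_replicates=("replicate", "count")))

    # drift statistic per cell
    Fs = []
    for (sch, rat, cls), g in df.groupby(["scheme", "ratio", "cell_class"]):
        p = g["final_altruism"].to_numpy()
        if p.size >= 2:
            dv = standardized_variance(p)
            F, defined = dv.F, dv.defined
        else:  # a single defined replicate carries no variance information
            F, defined = float("nan"), False
        Fs.append({"scheme": sch, "ratio": rat, "cell_class": cls,
                   "F": F, "defined": defined})
    F_table = pd.DataFrame(Fs)

    # diagonal altruism vs the neutral initial value 0.5
    wilcoxon = {}
    for (scheme, ratio), g in df[df["cell_class"] == "diagonal"].groupby(["scheme", "ratio"]):
        d = g["final_altruism"].to_numpy() - 0.5
        if np.allclose(d, 0):
            wilcoxon[(scheme, ratio)] = 1.0
        else:
            wilcoxon[(scheme, ratio)] = float(stats.wilcoxon(d).pvalue)

    # F comparison between diagonal and off-diagonal classes
    comparisons = {}
    F_def = F_table[F_table["defined"]]
    for cls in ("above", "below"):
        a = F_def.loc[F_def["cell_class"] == "diagonal", "F"].to_numpy()
        b = F_def.loc[F_def["cell_class"] == cls, "F"].to_numpy()
        if a.size and b.size:
            comparisons[f"diagonal_vs_{cls}"] = float(
                stats.mannwhitneyu(a, b, alternative="greater").pvalue)

    # mutation-selection-balance correlations per sign branch
    means = df.groupby(["scheme", "ratio"], as_index=False).agg(
        final_altruism=("final_altruism", "mean"), r_minus_ratio=("r_minus_ratio", "first"))
    correlations = {}
    for name, mask in (("negative_branch", means["r_minus_ratio"] < 0),
                       ("positive_branch", means["r_minus_ratio"] > 0)):
        sub = means[mask]
        if len(sub) >= 2 and sub["r_minus_ratio"].nunique() >= 2 \
                and sub["final_altruism"].nunique() >= 2:
            correlations[name] = float(
                stats.pearsonr(sub["r_minus_ratio"], sub["final_altruism"]).statistic)
    return {
        "cell_summary": cell,
        "drift_F": F_table,
        "diagonal_wilcoxon_p": wilcoxon,
        "F_class_comparison_p": comparisons,
        "pearson": correlations,
    }
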