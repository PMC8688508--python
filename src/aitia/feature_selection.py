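"""Feature selection: Fisher pre-filter, TAGA, expert merge, set ranking.

The combinatorial selector is a tabu asexual genetic algorithm (TAGA): a
fixed-cardinality subset search over the 12 features with the highest
Fisher scores, evolving chromosomes by single-feature swap mutations and
refusing swaps found on a FIFO tabu list of recently tested moves.  Fitness
is the minimum-redundancy maximum-relevance (mRMR) difference: mean mutual
information between selected features and the outcome minus mean pairwise
mutual information among selected features.  The selector is deliberately
classifier-agnostic, so the chosen features are not biased toward any one
model in the battery.

Because a genetic search is stochastic, each cardinality is re-run
(default 30 times) and the final subset takes the features selected most
frequently across runs (ties broken by higher Fisher score, then name).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import mutual_info_score

from .cohort_stats import FeatureSet

__all__ = [
    "TagaConfig",
    "fisher_scores",
    "taga_select",
    "build_taga_sets",
    "merge_expert_set",
    "rank_feature_sets",
    "RankingTable",
    "DEFAULT_EXPERT_FEATURES",
]

#: The expert-chosen final set shipped as the default configuration:
#: height, MAP, EILP, time-to-treat, time downgraded, prior surgeries.
DEFAULT_EXPERT_FEATURES = (
    "height_group",
    "map_group",
    "eilp_group",
    "ttt_group",
    "tdg_group",
    "prior_surgery",
)


@dataclasses.dataclass(frozen=True)
class TagaConfig:
    pool_size: int = 12
    lam: int = 6              # target subset cardinality, 2..10 in the sweep
    runs: int = 30
    population: int = 50
    generations: int = 100
    tabu_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam > self.pool_size:
            raise ValueError("lambda cannot exceed the Fisher pool size")
        if self.runs < 1:
            raise ValueError("runs must be at least 1")
        if self.lam < 1:
            raise ValueError("lambda must be at least 1")


_VAR_FLOOR = 1e-12


def fisher_scores(matrix: pd.DataFrame, labels: np.ndarray) -> pd.Series:
    """Two-class Fisher score per feature on the ordinal encodings.

    score_j = sum_c n_c (mu_jc - mu_j)^2 / sum_c n_c var_jc, with the
    denominator floored so a feature constant within both classes (zero
    between- and within-class variance) scores 0.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("Fisher scores require exactly two classes")
    X = matrix.to_numpy(dtype=float)
    scores = {}
    for j, col in enumerate(matrix.columns):
        v = X[:, j]
        mu = v.mean()
        num = den = 0.0
        for c in classes:
            vc = v[y == c]
            num += vc.size * (vc.mean() - mu) ** 2
            den += vc.size * vc.var()
        scores[col] = 0.0 if num == 0 else num / max(den, _VAR_FLOOR)
    return pd.Series(scores)


def _mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in discrete mutual information in nats (values taken as levels)."""
    _, ca = np.unique(a, return_inverse=True)
    _, cb = np.unique(b, return_inverse=True)
    return float(mutual_info_score(ca, cb))


def _mrmr_fitness(chrom: tuple[int, ...], mi_label: np.ndarray,
                  mi_pair: np.ndarray) -> float:
    idx = list(chrom)
    relevance = mi_label[idx].mean()
    if len(idx) < 2:
        return relevance
    pairs = [mi_pair[i, j] for i, j in itertools.combinations(idx, 2)]
    return relevance - float(np.mean(pairs))


def _taga_run(pool: list[str], mi_label: np.ndarray, mi_pair: np.ndarray,
              lam: int, population: int, generations: int, tabu_size: int,
              rng: np.random.Generator) -> tuple[tuple[int, ...], list[float]]:
    """One GA run on the Fisher pool; returns best chromosome + best-fitness trace."""
    p = len(pool)
    pop = [tuple(sorted(rng.choice(p, size=lam, replace=False)))
           for _ in range(population)]
    fit = {c: _mrmr_fitness(c, mi_label, mi_pair) for c in set(pop)}
    tabu: list[tuple[int, int]] = []  # FIFO of (removed, added) swaps
    trace: list[float] = []

    for _ in range(generations):
        offspring = []
        for chrom in pop:
            out_pool = [i for i in range(p) if i not in chrom]
            if lam == p or not out_pool:
                offspring.append(chrom)
                continue
            child = chrom
            for _attempt in range(2 * p):
                rm = int(chrom[rng.integers(lam)])
                add = int(out_pool[rng.integers(len(out_pool))])
                if tabu_size and (rm, add) in tabu:
                    continue
                if tabu_size:
                    tabu.append((rm, add))
                    if len(tabu) > tabu_size:
                        tabu.pop(0)
                child = tuple(sorted(set(chrom) - {rm} | {add}))
                break
            offspring.append(child)
        for c in offspring:
            if c not in fit:
                fit[c] = _mrmr_fitness(c, mi_label, mi_pair)
        # (mu + lambda) survival with implicit elitism: best always survives
        merged = sorted(set(pop) | set(offspring), key=lambda c: (-fit[c], c))
        pop = merged[:population]
        trace.append(fit[pop[0]])
    best = max(pop, key=lambda c: fit[c])
    return best, trace


def taga_select(matrix: pd.DataFrame, labels: np.ndarray, config: TagaConfig,
                name: str | None = None) -> FeatureSet:
    """Select a fixed-cardinality feature subset with the TAGA.

    Restricts to the ``pool_size`` top-Fisher features, runs the tabu
    asexual GA ``runs`` times, and returns the ``lam`` features with the
    highest selection frequency across runs (ties by Fisher score, then
    lexicographically).
    """
    fisher = fisher_scores(matrix, labels)
    pool = list(fisher.sort_values(ascending=False, kind="stable")
                .index[: config.pool_size])
    if config.lam > len(pool):
        raise ValueError("lambda exceeds the available Fisher pool")
    y = np.asarray(labels)
    Xp = matrix[pool].to_numpy()
    mi_label = np.array([_mutual_info(Xp[:, i], y) for i in range(len(pool))])
    mi_pair = np.zeros((len(pool), len(pool)))
    for i, j in itertools.combinations(range(len(pool)), 2):
        mi_pair[i, j] = mi_pair[j, i] = _mutual_info(Xp[:, i], Xp[:, j])

    rng = np.random.default_rng(config.seed)
    counts = np.zeros(len(pool))
    for _ in range(config.runs):
        best, _trace = _taga_run(pool, mi_label, mi_pair, config.lam,
                                 config.population, config.generations,
                                 config.tabu_size, rng)
        counts[list(best)] += 1

    order = sorted(
        range(len(pool)),
        key=lambda i: (-counts[i], -fisher[pool[i]], pool[i]),
    )
    chosen = tuple(sorted(pool[i] for i in order[: config.lam]))
    return FeatureSet(name or f"TAGA {config.lam}", chosen, "taga")


def build_taga_sets(matrix: pd.DataFrame, labels: np.ndarray,
                    base: TagaConfig, lam_range: range = range(2, 11)
                    ) -> list[FeatureSet]:
    """One TAGA set per cardinality (default 2..10, giving 9 sets)."""
    sets = []
    for lam in lam_range:
        cfg = dataclasses.replace(base, lam=lam, seed=base.seed + lam)
        sets.append(taga_select(matrix, labels, cfg, name=f"TAGA {lam}"))
    return sets


def merge_expert_set(stats_best: FeatureSet, taga_best: FeatureSet,
                     expert_choice: list[str]) -> FeatureSet:
    """Validate the clinician-chosen combination of the two best sets.

    The expert choice is configuration, not computation: it must be a
    subset of the union of the best statistical and best TAGA sets.
    """
    union = set(stats_best.features) | set(taga_best.features)
    outside = [f for f in expert_choice if f not in union]
    if outside:
        raise ValueError(
            f"expert features outside the STAT/TAGA union: {outside}")
    return FeatureSet("STAT + TAGA + Expert", tuple(expert_choice), "merged")


@dataclasses.dataclass
class RankingTable:
    """Cross-classifier AUC ranking of candidate feature sets."""

    auc: pd.DataFrame          # set x classifier AUC
    ranks: pd.DataFrame        # set x classifier rank (1 = best)
    summed_rank: pd.Series
    winner: str


def rank_feature_sets(auc_table: pd.DataFrame) -> RankingTable:
    """Rank sets by AUC within each classifier; winner = lowest summed rank.

    Ties within a classifier get average ranks; summed-rank ties are broken
    by higher mean AUC across classifiers, then by name.
    """
    if auc_table.isna().any().any():
        raise ValueError("AUC table has missing cells")
    ranks = auc_table.apply(lambda col: rankdata(-col.to_numpy()), axis=0)
    ranks = pd.DataFrame(ranks, index=auc_table.index,
                         columns=auc_table.columns)
    summed = ranks.sum(axis=1)
    mean_auc = auc_table.mean(axis=1)
    order = sorted(auc_table.index,
                   key=lambda s: (summed[s], -mean_auc[s], str(s)))
    return RankingTable(auc=auc_table, ranks=ranks, summed_rank=summed,
                        winner=order[0])
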