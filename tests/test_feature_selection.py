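"""Fisher scores, TAGA subset search, expert merge and set ranking."""

import numpy as np
import pandas as pd
import pytest

import aitia.feature_selection as fsel
from aitia import (DEFAULT_EXPERT_FEATURES, TagaConfig, build_taga_sets,
                   fisher_scores, merge_expert_set, rank_feature_sets,
                   taga_select)
from aitia.cohort_stats import FeatureSet
from aitia.feature_selection import _mrmr_fitness, _mutual_info, _taga_run


def _planted_fixture(seed=5, n=200, noise_features=9):
    """3 noisy-copy predictive features among independent noise.

    Each signal is the label half the time and a random bit otherwise:
    noisy enough that each signal's relevance to the label exceeds twice
    the signals' mutual redundancy, making the full signal triple the
    mRMR optimum, yet far above the noise features' relevance.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    cols = {}
    for i in range(3):
        flip = rng.random(n) < 0.5
        cols[f"signal{i}"] = np.where(flip, rng.integers(0, 2, n), y)
    for i in range(noise_features):
        cols[f"noise{i}"] = rng.integers(0, 3, size=n)
    return pd.DataFrame(cols), y


# --- Fisher score --------------------------------------------------------

def test_constant_feature_scores_zero():
    m = pd.DataFrame({"c": [2, 2, 2, 2], "x": [0, 1, 0, 1]})
    y = np.array([0, 0, 1, 1])
    assert fisher_scores(m, y)["c"] == 0.0


def test_label_copy_scores_highest():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 100)
    m = pd.DataFrame({"copy": y, "noise": rng.integers(0, 3, 100)})
    s = fisher_scores(m, y)
    assert s["copy"] == s.max()


def test_separated_beats_interleaved():
    y = np.array([0, 0, 1, 1])
    m = pd.DataFrame({"sep": [0, 0, 1, 1], "mix": [0, 1, 0, 1]})
    s = fisher_scores(m, y)
    assert s["sep"] > s["mix"]


def test_single_class_rejected():
    m = pd.DataFrame({"x": [1, 2, 3]})
    with pytest.raises(ValueError):
        fisher_scores(m, np.array([1, 1, 1]))


# --- mutual information --------------------------------------------------

def test_mutual_information_nonnegative_and_small_when_independent():
    rng = np.random.default_rng(4)
    a = rng.integers(0, 3, 500)
    b = rng.integers(0, 3, 500)
    mi = _mutual_info(a, b)
    assert 0 <= mi < 0.05  # plug-in bias bound at n = 500


# --- TAGA ----------------------------------------------------------------

def test_lambda_exceeding_pool_rejected():
    with pytest.raises(ValueError):
        TagaConfig(lam=13, pool_size=12)


def test_taga_recovers_planted_features():
    m, y = _planted_fixture(seed=5)
    cfg = TagaConfig(lam=3, runs=30, population=20, generations=15, seed=5)
    selected = taga_select(m, y, cfg)
    assert set(selected.features) == {"signal0", "signal1", "signal2"}


def test_taga_cardinality_and_pool_containment():
    m, y = _planted_fixture(seed=2, noise_features=15)
    fisher = fisher_scores(m, y)
    pool = set(fisher.sort_values(ascending=False).index[:12])
    for lam in (2, 5, 8):
        cfg = TagaConfig(lam=lam, runs=3, population=10, generations=5, seed=1)
        s = taga_select(m, y, cfg)
        assert len(s.features) == lam
        assert set(s.features) <= pool


def test_frequency_aggregation_rule(monkeypatch):
    m, y = _planted_fixture(seed=1, noise_features=5)
    # script the per-run winners: {A,B}, {A,B}, {A,C} as pool indices
    scripted = iter([(0, 1), (0, 1), (0, 2)])
    monkeypatch.setattr(fsel, "_taga_run",
                        lambda *a, **k: (next(scripted), []))
    cfg = TagaConfig(lam=2, runs=3, population=5, generations=1, seed=0)
    s = taga_select(m, y, cfg)
    fisher = fisher_scores(m, y)
    pool = list(fisher.sort_values(ascending=False, kind="stable").index[:12])
    assert set(s.features) == {pool[0], pool[1]}


def test_elitism_best_fitness_nondecreasing():
    m, y = _planted_fixture(seed=7)
    fisher = fisher_scores(m, y)
    pool = list(fisher.sort_values(ascending=False, kind="stable").index[:12])
    Xp = m[pool].to_numpy()
    mi_label = np.array([_mutual_info(Xp[:, i], y) for i in range(len(pool))])
    mi_pair = np.zeros((len(pool), len(pool)))
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            mi_pair[i, j] = mi_pair[j, i] = _mutual_info(Xp[:, i], Xp[:, j])
    rng = np.random.default_rng(3)
    _, trace = _taga_run(pool, mi_label, mi_pair, lam=4, population=10,
                         generations=20, tabu_size=5, rng=rng)
    assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))


def test_tabu_free_single_run_matches_plain_ga():
    """With tabu_size=0 and runs=1 the selector is a plain asexual GA."""

    def plain_ga_run(pool, mi_label, mi_pair, lam, population, generations, rng):
        p = len(pool)
        pop = [tuple(sorted(rng.choice(p, size=lam, replace=False)))
               for _ in range(population)]
        fit = {c: _mrmr_fitness(c, mi_label, mi_pair) for c in set(pop)}
        for _ in range(generations):
            offspring = []
            for chrom in pop:
                out_pool = [i for i in range(p) if i not in chrom]
                rm = int(chrom[rng.integers(lam)])
                add = int(out_pool[rng.integers(len(out_pool))])
                offspring.append(tuple(sorted(set(chrom) - {rm} | {add})))
            for c in offspring:
                if c not in fit:
                    fit[c] = _mrmr_fitness(c, mi_label, mi_pair)
            pop = sorted(set(pop) | set(offspring),
                         key=lambda c: (-fit[c], c))[:population]
        return max(pop, key=lambda c: fit[c])

    m, y = _planted_fixture(seed=9)
    fisher = fisher_scores(m, y)
    pool = list(fisher.sort_values(ascending=False, kind="stable").index[:12])
    Xp = m[pool].to_numpy()
    mi_label = np.array([_mutual_info(Xp[:, i], y) for i in range(len(pool))])
    mi_pair = np.zeros((len(pool), len(pool)))
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            mi_pair[i, j] = mi_pair[j, i] = _mutual_info(Xp[:, i], Xp[:, j])
    best_taga, _ = _taga_run(pool, mi_label, mi_pair, lam=3, population=12,
                             generations=10, tabu_size=0,
                             rng=np.random.default_rng(21))
    best_plain = plain_ga_run(pool, mi_label, mi_pair, lam=3, population=12,
                              generations=10, rng=np.random.default_rng(21))
    assert best_taga == best_plain


def test_nine_taga_sets_with_fixed_cardinalities():
    m, y = _planted_fixture(seed=3, noise_features=12)
    base = TagaConfig(runs=2, population=8, generations=3, seed=4)
    sets = build_taga_sets(m, y, base)
    assert len(sets) == 9
    assert [s.name for s in sets] == [f"TAGA {k}" for k in range(2, 11)]
    assert [len(s.features) for s in sets] == list(range(2, 11))


# --- expert merge --------------------------------------------------------

def test_expert_subset_accepted():
    stats_best = FeatureSet("S", ("height_group", "map_group"), "stats")
    taga_best = FeatureSet("T", ("eilp_group", "ttt_group"), "taga")
    merged = merge_expert_set(stats_best, taga_best,
                              ["height_group", "ttt_group"])
    assert merged.provenance == "merged"
    assert merged.features == ("height_group", "ttt_group")


def test_expert_outside_union_rejected():
    stats_best = FeatureSet("S", ("height_group",), "stats")
    taga_best = FeatureSet("T", ("eilp_group",), "taga")
    with pytest.raises(ValueError, match="outside"):
        merge_expert_set(stats_best, taga_best, ["smoking_group"])


def test_default_expert_configuration():
    assert set(DEFAULT_EXPERT_FEATURES) == {
        "height_group", "map_group", "eilp_group", "ttt_group",
        "tdg_group", "prior_surgery"}


# --- ranking -------------------------------------------------------------

def test_dominating_set_wins():
    auc = pd.DataFrame({"clf1": [0.9, 0.7], "clf2": [0.8, 0.6]},
                       index=["best", "other"])
    table = rank_feature_sets(auc)
    assert table.winner == "best"
    assert table.summed_rank["best"] == 2  # rank 1 in each of 2 classifiers


def test_summed_rank_tie_broken_by_mean_auc():
    auc = pd.DataFrame({"c1": [0.8, 0.7, 0.6], "c2": [0.7, 0.8, 0.6]},
                       index=["s1", "s2", "s3"])
    table = rank_feature_sets(auc)
    assert table.summed_rank["s1"] == table.summed_rank["s2"] == 3
    assert table.summed_rank["s3"] == 6
    assert table.winner == "s1"  # equal mean AUC -> first by name


def test_identical_columns_average_ranks():
    auc = pd.DataFrame({"c1": [0.8, 0.8], "c2": [0.7, 0.7]},
                       index=["a", "b"])
    table = rank_feature_sets(auc)
    assert table.summed_rank["a"] == table.summed_rank["b"] == 3.0
    assert table.winner == "a"


def test_missing_cells_rejected():
    auc = pd.DataFrame({"c1": [0.8, np.nan]}, index=["a", "b"])
    with pytest.raises(ValueError):
        rank_feature_sets(auc)
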