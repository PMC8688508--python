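"""Instance hardness, the four hardness measures, correlations and sweeps."""

import numpy as np
import pandas as pd
import pytest

from aitia import (class_likelihood_difference, correlate_hardness,
                   difficulty_sweep, disjunct_measures, hardness_profile,
                   instance_hardness, kdn)
from aitia.interrogation import HardnessProfile


# --- brute-force oracles -------------------------------------------------

def brute_kdn(X, y, k):
    """Explicit neighbour enumeration; distance ties broken by index."""
    X = np.asarray(X, float)
    rng_ = X.max(axis=0) - X.min(axis=0)
    rng_[rng_ == 0] = 1.0
    Xn = (X - X.min(axis=0)) / rng_
    out = []
    for i in range(len(X)):
        d = [(((Xn[i] - Xn[j]) ** 2).sum(), j)
             for j in range(len(X)) if j != i]
        d.sort()
        nbrs = [j for _, j in d[:k]]
        out.append(np.mean([y[j] != y[i] for j in nbrs]))
    return np.array(out)


def brute_cld(X, y, alpha=1.0):
    X = np.asarray(X)
    y = np.asarray(y)
    classes = np.unique(y)
    out = []
    for i in range(len(X)):
        cl = {}
        for c in classes:
            prod = 1.0
            for j in range(X.shape[1]):
                levels = np.unique(X[:, j])
                count = np.sum((X[y == c, j] == X[i, j]))
                prod *= (count + alpha) / ((y == c).sum() + alpha * len(levels))
            cl[c] = prod
        own = cl[y[i]]
        rival = max(v for c, v in cl.items() if c != y[i])
        out.append(own - rival)
    return np.array(out)


@pytest.mark.parametrize("seed", range(8))
def test_kdn_and_cld_match_bruteforce_on_small_fixtures(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(7, 13))
    p = int(rng.integers(1, 4))
    X = rng.integers(0, 2, size=(n, p)).astype(float)
    y = rng.integers(0, 2, size=n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    k = 3
    np.testing.assert_allclose(kdn(X, y, k=k), brute_kdn(X, y, k))
    np.testing.assert_allclose(class_likelihood_difference(X, y),
                               brute_cld(X, y))


# --- instance hardness ---------------------------------------------------

def test_instance_hardness_arithmetic():
    y = np.array([1, 0])
    # record 0: correct by all 4; record 1: wrong by 1 of 4
    probs = pd.DataFrame({"a": [0.9, 0.2], "b": [0.8, 0.1],
                          "c": [0.7, 0.6], "d": [0.6, 0.3]})
    h = instance_hardness(probs, y)
    assert h[0] == 0.0
    assert h[1] == pytest.approx(0.25)


def test_relabelling_complements_hardness():
    rng = np.random.default_rng(0)
    probs = pd.DataFrame(rng.random((10, 8)))
    probs = probs.mask(np.isclose(probs, 0.5), 0.51)  # avoid threshold ties
    y = rng.integers(0, 2, 10)
    h = instance_hardness(probs, y)
    h_flip = instance_hardness(probs, 1 - y)
    np.testing.assert_allclose(h + h_flip, 1.0)


def test_hardness_invariant_to_classifier_order():
    rng = np.random.default_rng(1)
    probs = pd.DataFrame(rng.random((12, 5)), columns=list("abcde"))
    y = rng.integers(0, 2, 12)
    h1 = instance_hardness(probs, y)
    h2 = instance_hardness(probs[list("ecadb")], y)
    np.testing.assert_allclose(h1, h2)


def test_invalid_probability_rejected():
    probs = pd.DataFrame({"a": [0.5, 1.2]})
    with pytest.raises(ValueError):
        instance_hardness(probs, np.array([0, 1]))


# --- KDN -----------------------------------------------------------------

def test_kdn_two_clusters():
    X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    scores = kdn(X, y, k=3)
    # point at 2: nearest three are 1, 0 and 10; one disagrees
    assert scores[2] == pytest.approx(1 / 3)


def test_kdn_single_label_all_zero():
    rng = np.random.default_rng(2)
    X = rng.random((20, 3))
    scores = kdn(X, np.ones(20, int), k=5)
    np.testing.assert_allclose(scores, 0.0)


def test_kdn_needs_enough_records():
    with pytest.raises(ValueError):
        kdn(np.zeros((4, 2)), np.array([0, 1, 0, 1]), k=5)


# --- disjuncts -----------------------------------------------------------

def test_disjunct_size_extremes():
    X = np.array([[0.0], [0.0], [0.0], [0.0], [0.0], [10.0]])
    y = np.array([0, 0, 0, 0, 0, 1])
    ds, _ = disjunct_measures(X, y)
    assert ds[0] == 1.0   # member of the largest pure leaf
    assert ds[5] == 0.0   # singleton leaf


def test_disjunct_class_percentage_small_leaf():
    # 4 records cannot be split at min leaf size 5: one covering leaf,
    # 3 of 4 share the first record's class
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0, 0, 0, 1])
    _, dcp = disjunct_measures(X, y)
    assert dcp[0] == pytest.approx(0.75)
    assert dcp[3] == pytest.approx(0.25)


def test_disjunct_measures_order_invariant():
    rng = np.random.default_rng(4)
    X = rng.integers(0, 3, size=(30, 4)).astype(float)
    y = rng.integers(0, 2, 30)
    ds, dcp = disjunct_measures(X, y)
    perm = rng.permutation(30)
    ds_p, dcp_p = disjunct_measures(X[perm], y[perm])
    np.testing.assert_allclose(ds_p, ds[perm])
    np.testing.assert_allclose(dcp_p, dcp[perm])


# --- CLD -----------------------------------------------------------------

def test_cld_laplace_counts():
    # single feature, class A all 0s, class B all 1s, 4 records each:
    # CL(A) = (4+1)/(4+2) = 5/6, CL(B) = (0+1)/(4+2) = 1/6
    X = np.array([[0]] * 4 + [[1]] * 4)
    y = np.array([0] * 4 + [1] * 4)
    cld = class_likelihood_difference(X, y, smoothing=1)
    assert cld[0] == pytest.approx(5 / 6 - 1 / 6)


def test_cld_invariant_under_global_relabel():
    # swapping every label swaps the class-conditional tables exactly, so
    # own-vs-rival differences are unchanged in the two-class case
    X = np.array([[0], [0], [1], [1], [0]])
    y = np.array([0, 0, 1, 1, 1])
    cld = class_likelihood_difference(X, y)
    flipped = class_likelihood_difference(X, 1 - y)
    np.testing.assert_allclose(flipped, cld)


def test_cld_zero_at_symmetric_midpoint():
    # value 1 occurs once in each class of size 2: likelihoods coincide
    X = np.array([[0], [1], [2], [1]])
    y = np.array([0, 0, 1, 1])
    cld = class_likelihood_difference(X, y)
    assert cld[1] == pytest.approx(0.0)
    assert cld[3] == pytest.approx(0.0)


# --- profile & correlation ----------------------------------------------

def test_correlation_identity_when_hardness_equals_kdn():
    rng = np.random.default_rng(6)
    v = rng.random(20)
    frame = pd.DataFrame({"instance_hardness": v, "kdn": v,
                          "ds": rng.random(20), "dcp": rng.random(20),
                          "cld": rng.random(20)})
    rho = correlate_hardness(HardnessProfile(frame))
    assert rho["kdn"] == pytest.approx(1.0)
    assert ((rho.dropna() >= -1) & (rho.dropna() <= 1)).all()


def test_constant_hardness_rejected():
    frame = pd.DataFrame({"instance_hardness": np.zeros(15),
                          "kdn": np.random.default_rng(0).random(15),
                          "ds": np.zeros(15), "dcp": np.zeros(15),
                          "cld": np.zeros(15)})
    with pytest.raises(ValueError, match="constant"):
        correlate_hardness(HardnessProfile(frame))


def test_overlap_cohort_correlation_signs():
    from aitia import (CohortSpec, CVConfig, default_battery,
                       generate_raw_cohort, nested_cv, preprocess_cohort)
    from aitia.preprocessing import PROCESSED_FEATURES
    df = generate_raw_cohort(
        CohortSpec(n_records=300, minority_fraction=0.3, overlap=0.6,
                   seed=4, missing_rate_faam_eilp=0))
    m, _ = preprocess_cohort(df, drop_outliers=False)
    y = m["outcome"].to_numpy()
    res = nested_cv(m, y, default_battery(reduced=True), PROCESSED_FEATURES,
                    CVConfig(repeats=2, seed=2))
    prof = hardness_profile(m[PROCESSED_FEATURES], y, res.mean_oof)
    rho = correlate_hardness(prof)
    assert rho["kdn"] > 0
    assert rho["cld"] < 0


# --- difficulty sweep ----------------------------------------------------

def _sweep_inputs(seed=9, n=60):
    """Localised overlap: label noise only where the score marks 'hard'."""
    rng = np.random.default_rng(seed)
    hardness = np.sort(rng.random(n))
    y = (rng.random(n) < 0.5).astype(int)
    # model probabilities: accurate on easy half, random on hard half
    probs = {}
    for mdl in ("m1", "m2"):
        p = np.where(hardness < 0.5,
                     0.15 + 0.2 * rng.random(n) + 0.5 * y,
                     rng.random(n))
        probs[mdl] = np.clip(p, 0, 1)
    return pd.DataFrame(probs), y, hardness


def test_full_inclusion_reproduces_overall_auc():
    from sklearn.metrics import roc_auc_score
    probs, y, hardness = _sweep_inputs()
    curve = difficulty_sweep(probs, y, hardness, "accumulating-hard")
    last = curve.frame.iloc[-1]
    assert last["n"] == len(y)
    for mdl in probs.columns:
        assert last[mdl] == pytest.approx(
            roc_auc_score(y, probs[mdl]), abs=1e-12)


def test_single_class_subsets_excluded():
    probs = pd.DataFrame({"m": [0.1, 0.2, 0.8, 0.9]})
    y = np.array([0, 0, 1, 1])
    scores = np.array([0.0, 0.1, 0.5, 0.9])
    curve = difficulty_sweep(probs, y, scores, "accumulating-hard")
    # thresholds 0.0 and 0.1 include only class 0: excluded from the curve
    assert curve.frame["threshold"].min() >= 0.5
    assert (curve.frame[["n_pos", "n_neg"]] > 0).all().all()


def test_easy_subset_auc_not_below_hard_subset():
    probs, y, hardness = _sweep_inputs(seed=9)
    easy = hardness < 0.5
    hard = ~easy
    from sklearn.metrics import roc_auc_score
    for mdl in probs.columns:
        auc_easy = roc_auc_score(y[easy], probs[mdl][easy])
        auc_hard = roc_auc_score(y[hard], probs[mdl][hard])
        assert auc_easy >= auc_hard


def test_empty_threshold_grid_rejected():
    probs = pd.DataFrame({"m": [0.1, 0.9]})
    with pytest.raises(ValueError):
        difficulty_sweep(probs, np.array([0, 1]), np.array([0.2, 0.8]),
                         "accumulating-hard", thresholds=np.array([]))


def test_shedding_easy_direction_monotone_counts():
    probs, y, hardness = _sweep_inputs(seed=11)
    curve = difficulty_sweep(probs, y, hardness, "shedding-easy")
    ns = curve.frame["n"].to_numpy()
    assert (np.diff(ns) <= 0).all()
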