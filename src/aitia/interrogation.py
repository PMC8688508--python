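"""Trust by interrogation: instance hardness and class-overlap measures.

Rather than stopping at cohort-level metrics, the interrogation stage asks
*which records* a model battery fails on and *why*.  Each record gets an
instance-hardness score — the fraction of trialled classifiers whose mean
out-of-fold probability (thresholded at 0.5) mislabels it — plus four
data-level hardness measures:

- KDN (k-disagreeing neighbours): fraction of the record's k nearest
  neighbours carrying a different label; localised class overlap.
- DS (disjunct size): normalised size of the leaf covering the record in
  an unpruned decision tree grown to purity; small disjuncts flag records
  needing exceptional rules.
- DCP (disjunct class percentage): fraction of the covering leaf of a
  pruned tree (minimum leaf size 5) sharing the record's class.
- CLD (class-likelihood difference): naive-Bayes likelihood of the record
  under its own class minus the best rival class, with Laplace smoothing;
  global class overlap.

Spearman correlations between instance hardness and each measure identify
the dominant source of difficulty, and difficulty sweeps trace each
model's AUC as records are accumulated from easy to hard (or shed from the
easy end), exposing which classifiers degrade first as overlap grows.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "HardnessProfile",
    "SweepCurve",
    "instance_hardness",
    "kdn",
    "disjunct_measures",
    "class_likelihood_difference",
    "hardness_profile",
    "correlate_hardness",
    "difficulty_sweep",
]


@dataclasses.dataclass
class HardnessProfile:
    """Per-record instance hardness and the four hardness measures."""

    frame: pd.DataFrame  # columns: instance_hardness, kdn, ds, dcp, cld

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=True, index_label="record")


def instance_hardness(oof_probabilities: pd.DataFrame, labels: np.ndarray
                      ) -> np.ndarray:
    """Fraction of classifiers mislabelling each record at threshold 0.5.

    ``oof_probabilities``: record x classifier mean out-of-fold probability
    of the positive class.  Invariant under classifier column order.
    """
    P = oof_probabilities.to_numpy(dtype=float)
    if ((P < 0) | (P > 1)).any() or np.isnan(P).any():
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels).astype(int).reshape(-1, 1)
    pred = (P >= 0.5).astype(int)
    return (pred != y).mean(axis=1)


def _scaled(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = (matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame)
         else np.asarray(matrix, dtype=float))
    rng_ = X.max(axis=0) - X.min(axis=0)
    rng_[rng_ == 0] = 1.0
    return (X - X.min(axis=0)) / rng_


def kdn(matrix: pd.DataFrame | np.ndarray, labels: np.ndarray, k: int = 5
        ) -> np.ndarray:
    """k-disagreeing neighbours on min-max-scaled encodings, self excluded.

    Distance ties (common on coarse ordinal encodings) are broken by
    record index, making the neighbour sets deterministic.
    """
    X = _scaled(matrix)
    y = np.asarray(labels)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} records")
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")  # ties by index
    out = np.empty(n)
    for i in range(n):
        nbrs = [j for j in order[i] if j != i][:k]
        out[i] = (y[nbrs] != y[i]).mean()
    return out


def disjunct_measures(matrix: pd.DataFrame | np.ndarray, labels: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Disjunct size (unpruned tree) and disjunct class percentage (pruned).

    DS(x) = (|leaf(x)| - 1) / (max_y |leaf(y)| - 1) from a tree grown to
    purity; if every leaf is a singleton DS is 0 everywhere.  DCP(x) is the
    fraction of x's covering leaf (minimum leaf size 5) sharing x's class.
    """
    X = (matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame)
         else np.asarray(matrix, dtype=float))
    y = np.asarray(labels)
    if X.shape[0] < 2:
        raise ValueError("disjunct measures need at least 2 records")

    unpruned = DecisionTreeClassifier(random_state=0).fit(X, y)
    leaf = unpruned.apply(X)
    sizes = pd.Series(leaf).map(pd.Series(leaf).value_counts()).to_numpy()
    max_size = sizes.max()
    ds = (np.zeros_like(sizes, dtype=float) if max_size <= 1
          else (sizes - 1) / (max_size - 1))

    pruned = DecisionTreeClassifier(min_samples_leaf=5, random_state=0).fit(X, y)
    pleaf = pruned.apply(X)
    dcp = np.empty(X.shape[0], dtype=float)
    for lf in np.unique(pleaf):
        mask = pleaf == lf
        members = y[mask]
        for cls in np.unique(members):
            dcp[mask & (y == cls)] = (members == cls).mean()
    return ds, dcp


def class_likelihood_difference(matrix: pd.DataFrame | np.ndarray,
                                labels: np.ndarray, smoothing: float = 1.0
                                ) -> np.ndarray:
    """CLD(x) = CL(x, own class) - max over rival classes of CL(x, rival).

    CL(x, c) = prod_i P(x_i | c) with additive (Laplace) smoothing over
    each feature's observed level set.  All features must be discrete.
    """
    X = (matrix.to_numpy() if isinstance(matrix, pd.DataFrame)
         else np.asarray(matrix))
    y = np.asarray(labels)
    classes = np.unique(y)
    n, p = X.shape
    cl = np.ones((n, classes.size))
    for j in range(p):
        col = X[:, j]
        levels = np.unique(col)
        if smoothing == 0 and any(
                np.setdiff1d(levels, np.unique(col[y == c])).size
                for c in classes):
            import warnings
            warnings.warn("level unseen in a class with smoothing=0; "
                          "zero likelihoods will result")
        for ci, c in enumerate(classes):
            colc = col[y == c]
            denom = colc.size + smoothing * levels.size
            for lv in levels:
                pr = ((colc == lv).sum() + smoothing) / denom
                cl[(col == lv), ci] *= pr
    own = np.array([np.where(classes == yi)[0][0] for yi in y])
    cl_own = cl[np.arange(n), own]
    rival = cl.copy()
    rival[np.arange(n), own] = -np.inf
    return cl_own - rival.max(axis=1)


def hardness_profile(matrix: pd.DataFrame, labels: np.ndarray,
                     oof_probabilities: pd.DataFrame, k: int = 5,
                     smoothing: float = 1.0) -> HardnessProfile:
    """Assemble the full per-record hardness profile."""
    ds, dcp = disjunct_measures(matrix, labels)
    frame = pd.DataFrame({
        "instance_hardness": instance_hardness(oof_probabilities, labels),
        "kdn": kdn(matrix, labels, k=k),
        "ds": ds,
        "dcp": dcp,
        "cld": class_likelihood_difference(matrix, labels, smoothing),
    })
    return HardnessProfile(frame)


def correlate_hardness(profile: HardnessProfile) -> pd.Series:
    """Spearman rho of each hardness measure against instance hardness."""
    f = profile.frame
    if len(f) < 10:
        raise ValueError("correlation needs at least 10 records")
    h = f["instance_hardness"].to_numpy()
    if np.ptp(h) == 0:
        raise ValueError("instance hardness is constant; correlation undefined")
    out = {}
    for m in ("kdn", "ds", "dcp", "cld"):
        v = f[m].to_numpy()
        if np.ptp(v) == 0:
            out[m] = np.nan
        else:
            out[m] = float(stats.spearmanr(h, v).statistic)
    return pd.Series(out)


@dataclasses.dataclass
class SweepCurve:
    """AUC of each model across a hardness-measure threshold sweep."""

    frame: pd.DataFrame  # threshold, n_pos, n_neg, one AUC column per model
    direction: str       # accumulating-hard | shedding-easy

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def difficulty_sweep(mean_oof_probabilities: pd.DataFrame, labels: np.ndarray,
                     measure_scores: np.ndarray, direction: str,
                     thresholds: np.ndarray | None = None,
                     higher_is_harder: bool = True) -> SweepCurve:
    """AUC per model on record subsets defined by a hardness threshold.

    ``accumulating-hard`` starts from the easiest records and includes
    every record with score <= t (>= t when ``higher_is_harder`` is False);
    ``shedding-easy`` keeps only records harder than t.  Thresholds default
    to the sorted unique measure values; points where only one class
    survives carry NaN AUCs and are dropped from the curve.
    """
    if direction not in ("accumulating-hard", "shedding-easy"):
        raise ValueError(f"unknown direction: {direction!r}")
    scores = np.asarray(measure_scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.unique(scores)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    if not higher_is_harder:
        scores, thresholds = -scores, np.sort(-thresholds)

    rows = []
    for t in thresholds:
        if direction == "accumulating-hard":
            mask = scores <= t
        else:
            mask = scores >= t
        if not mask.any():
            continue
        yt = y[mask]
        row = {"threshold": float(t) if higher_is_harder else float(-t),
               "n_pos": int((yt == 1).sum()), "n_neg": int((yt == 0).sum()),
               "n": int(mask.sum())}
        if np.unique(yt).size < 2:
            continue  # AUC undefined: point excluded from the curve
        for m in mean_oof_probabilities.columns:
            row[m] = float(roc_auc_score(
                yt, mean_oof_probabilities[m].to_numpy()[mask]))
        rows.append(row)
    return SweepCurve(frame=pd.DataFrame(rows), direction=direction)
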