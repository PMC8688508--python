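"""Statistical characterisation of the processed cohort.

Normality screening (Kolmogorov-Smirnov and Shapiro-Wilk), between-outcome
tests (Mann-Whitney U with SPSS-style Z for the ordinal features, Pearson
chi-square for the binary ones), a Spearman co-linearity screen, and the
construction of the statistically-derived candidate feature sets at a
ladder of alpha thresholds while keeping co-linear pairs apart.

All tests are two-sided.  The Mann-Whitney Z uses the tie-corrected normal
approximation without continuity correction (the form under which Z values
are conventionally reported); its p-value is exact for small untied
samples and asymptotic otherwise.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import PROCESSED_FEATURES

__all__ = [
    "normality_tests",
    "rank_test",
    "association_test",
    "colinearity_screen",
    "build_stats_feature_sets",
    "cohort_stats_report",
    "StatsReport",
    "FeatureSet",
    "BINARY_FEATURES",
    "ORDINAL_FEATURES",
]

#: Binary (chi-square) vs ordinal (rank-test) processed features.
BINARY_FEATURES = ["alcohol_group", "prior_injury", "prior_surgery",
                   "prior_inpatient_rehab", "comorbidity"]
ORDINAL_FEATURES = [f for f in PROCESSED_FEATURES if f not in BINARY_FEATURES]


@dataclasses.dataclass(frozen=True)
class FeatureSet:
    """A named subset of processed features with provenance."""

    name: str
    features: tuple[str, ...]
    provenance: str  # stats | taga | expert | merged

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError(f"feature set {self.name!r} is empty")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"feature set {self.name!r} has duplicates")
        # membership in a concrete matrix schema is checked where the
        # matrix is available (e.g. nested_cv), not against a fixed list


@dataclasses.dataclass
class StatsReport:
    normality: pd.DataFrame        # feature x (ks_stat, ks_p, sw_stat, sw_p)
    between_group: pd.DataFrame    # feature x (test, statistic, z, p)
    correlation: pd.DataFrame      # feature x feature Spearman rho
    colinear_pairs: list[tuple[str, str]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "normality": self.normality.to_dict(orient="index"),
            "between_group": self.between_group.to_dict(orient="index"),
            "colinear_pairs": [list(p) for p in self.colinear_pairs],
        }, indent=2, default=float))


def normality_tests(values: np.ndarray) -> tuple[float, float, float, float]:
    """Kolmogorov-Smirnov (vs fitted normal) and Shapiro-Wilk statistics.

    Returns (ks_stat, ks_p, sw_stat, sw_p); requires n >= 3 and a
    non-constant sample.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise ValueError("normality tests require at least 3 values")
    if np.ptp(v) == 0:
        raise ValueError("normality tests are undefined for a constant vector")
    ks_stat, ks_p = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns above n=5000
        sw_stat, sw_p = stats.shapiro(v)
    return float(ks_stat), float(ks_p), float(sw_stat), float(sw_p)


def rank_test(group_a: np.ndarray, group_b: np.ndarray
              ) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U test; returns (U, Z, p).

    U is the statistic for ``group_a``; Z is the tie-corrected normal
    approximation without continuity correction, so swapping the groups
    negates Z and leaves p unchanged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             use_continuity=False, method="auto")
    u = float(res.statistic)
    n1, n2 = a.size, b.size
    nt = n1 + n2
    # tie correction on the pooled ranks
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = np.sum(counts ** 3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((nt + 1) - tie_term / (nt * (nt - 1)))
    mu = n1 * n2 / 2.0
    z = 0.0 if sigma2 == 0 else (u - mu) / np.sqrt(sigma2)
    return u, float(z), float(min(res.pvalue, 1.0))


def association_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency table.

    Warns when any expected count is below 5; raises on a zero margin.
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("contingency table has a zero margin")
    chi2, p, _, expected = stats.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        warnings.warn("expected count below 5; chi-square approximation is weak")
    return float(chi2), float(p)


def colinearity_screen(matrix: pd.DataFrame, threshold: float = 0.5
                       ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Spearman correlation matrix and the pairs with ``|rho| > threshold``.

    Constant features yield NaN correlations, which are reported as missing
    and never flagged.
    """
    feats = [c for c in matrix.columns if c != "outcome"]
    if len(feats) < 2:
        raise ValueError("co-linearity screen needs at least 2 features")
    corr = matrix[feats].corr(method="spearman")
    np.fill_diagonal(corr.values, 1.0)
    for c in feats:  # constant feature -> undefined, keep NaN off-diagonal
        if matrix[c].nunique(dropna=True) <= 1:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
            corr.loc[c, c] = 1.0
    pairs = [
        (a, b)
        for a, b in itertools.combinations(feats, 2)
        if np.isfinite(corr.loc[a, b]) and abs(corr.loc[a, b]) > threshold
    ]
    return corr, pairs


def cohort_stats_report(matrix: pd.DataFrame, threshold: float = 0.5
                        ) -> StatsReport:
    """Full statistical report for a processed matrix with ``outcome``."""
    y = matrix["outcome"].to_numpy()
    norm_rows, bg_rows = {}, {}
    for f in PROCESSED_FEATURES:
        v = matrix[f].to_numpy(dtype=float)
        try:
            ks_s, ks_p, sw_s, sw_p = normality_tests(v)
        except ValueError:
            ks_s = ks_p = sw_s = sw_p = np.nan
        norm_rows[f] = dict(ks_stat=ks_s, ks_p=ks_p, sw_stat=sw_s, sw_p=sw_p)
        if f in BINARY_FEATURES:
            table = pd.crosstab(matrix[f], matrix["outcome"])
            try:
                chi2, p = association_test(table.to_numpy())
            except ValueError:
                chi2, p = np.nan, np.nan
            bg_rows[f] = dict(test="chi2", statistic=chi2, z=np.nan, p=p)
        else:
            u, z, p = rank_test(v[y == 1], v[y == 0])
            bg_rows[f] = dict(test="mannwhitney", statistic=u, z=z, p=p)
    corr, pairs = colinearity_screen(matrix[PROCESSED_FEATURES], threshold)
    return StatsReport(
        normality=pd.DataFrame.from_dict(norm_rows, orient="index"),
        between_group=pd.DataFrame.from_dict(bg_rows, orient="index"),
        correlation=corr,
        colinear_pairs=pairs,
    )


def build_stats_feature_sets(report: StatsReport,
                             alphas: tuple[float, ...] = (0.05, 0.01, 0.001),
                             max_variants: int = 3) -> list[FeatureSet]:
    """Candidate feature sets from the between-group tests.

    For each alpha the base set contains every feature with p < alpha.
    When both members of a co-linear pair are significant, variants are
    enumerated keeping exactly one member per such pair; the default
    (first) variant keeps the smaller-p member.  At most ``max_variants``
    variants are kept per alpha, and no returned set contains a flagged
    pair.  Alphas yielding no significant feature are skipped.
    """
    pvals = report.between_group["p"]
    sets: list[FeatureSet] = []
    for alpha in alphas:
        sig = [f for f in pvals.index if np.isfinite(pvals[f]) and pvals[f] < alpha]
        if not sig:
            warnings.warn(f"no feature significant at alpha={alpha}; set skipped")
            continue
        conflicts = [(a, b) for a, b in report.colinear_pairs
                     if a in sig and b in sig]
        if not conflicts:
            sets.append(FeatureSet(f"Stats a={alpha}", tuple(sig), "stats"))
            continue

        def _resolve(flip: tuple[str, str] | None) -> tuple[str, ...]:
            # Greedily drop the larger-p member of each still-violated pair;
            # ``flip`` forces the opposite choice for one designated pair.
            kept = set(sig)
            while True:
                violated = [(a, b) for a, b in conflicts
                            if a in kept and b in kept]
                if not violated:
                    return tuple(f for f in sig if f in kept)
                a, b = violated[0]
                drop = a if pvals[a] > pvals[b] else b
                if flip == (a, b):
                    drop = b if drop == a else a
                kept.discard(drop)

        seen: set[tuple[str, ...]] = set()
        variant_idx = 0
        for flip in [None, *conflicts]:
            kept = _resolve(flip)
            if not kept or kept in seen:
                continue
            seen.add(kept)
            variant_idx += 1
            suffix = "" if variant_idx == 1 else f" v{variant_idx}"
            sets.append(FeatureSet(f"Stats a={alpha}{suffix}", kept, "stats"))
            if variant_idx >= max_variants:
                break
    return sets


def feature_sets_to_json(sets: list[FeatureSet], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        [dict(name=s.name, features=list(s.features), provenance=s.provenance)
         for s in sets], indent=2))


def feature_sets_from_json(path: str | Path) -> list[FeatureSet]:
    raw = json.loads(Path(path).read_text())
    return [FeatureSet(d["name"], tuple(d["features"]), d["provenance"])
            for d in raw]
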