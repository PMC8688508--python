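"""Raw-record preprocessing: derived variables, binning, imputation, outliers.

Turns the raw per-surgery table into the processed design matrix of 23
ordinal/categorical features used everywhere downstream.  Continuous fields
are grouped per public-health guideline cut-points (WHO BMI classes, AHA
2017 blood-pressure categories, UK drinking guidance, smoking bands from
the musculoskeletal literature) or, for the six pathway durations, per
cohort-tertile edges computed once and carried in a binning configuration.
Missing FAAM/EILP questionnaire scores are imputed with outcome-group
medians; isolated records are removed by a relative-density outlier score
thresholded at Q3 + 1.5 IQR.

All processed features are encoded as consecutive integers from 0 in
increasing clinical severity/magnitude order; binary flags are {0, 1}.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "PROCESSED_FEATURES",
    "FEATURE_LEVELS",
    "PATHWAY_VARIABLES",
    "BinConfig",
    "make_bin_config",
    "derive_features",
    "impute_missing",
    "outlier_scores",
    "remove_outliers",
    "preprocess_cohort",
    "OutlierReport",
]

DAYS_PER_MONTH = 30.44

#: The 23 processed feature columns, in canonical order.
PROCESSED_FEATURES = [
    "age_group",
    "rank_group",
    "height_group",
    "weight_group",
    "bmi_group",
    "bp_systolic_group",
    "bp_diastolic_group",
    "bp_overall_group",
    "map_group",
    "smoking_group",
    "alcohol_group",
    "faam_group",
    "eilp_group",
    "chronicity_group",
    "ttp_group",
    "ttd_group",
    "ttt_group",
    "tdg_group",
    "wait_time_group",
    "prior_injury",
    "prior_surgery",
    "prior_inpatient_rehab",
    "comorbidity",
]

#: Number of declared levels per processed feature (level set = 0..n-1).
FEATURE_LEVELS = {
    "age_group": 3,
    "rank_group": 3,
    "height_group": 3,
    "weight_group": 4,
    "bmi_group": 4,
    "bp_systolic_group": 4,
    "bp_diastolic_group": 3,
    "bp_overall_group": 4,
    "map_group": 3,
    "smoking_group": 4,
    "alcohol_group": 2,
    "faam_group": 5,
    "eilp_group": 5,
    "chronicity_group": 3,
    "ttp_group": 3,
    "ttd_group": 3,
    "ttt_group": 3,
    "tdg_group": 3,
    "wait_time_group": 3,
    "prior_injury": 2,
    "prior_surgery": 2,
    "prior_inpatient_rehab": 2,
    "comorbidity": 2,
}

#: Pathway duration -> (start date column, end date column).
PATHWAY_VARIABLES = {
    "chronicity": ("date_onset", "date_surgery"),
    "ttp": ("date_onset", "date_presentation"),
    "ttd": ("date_presentation", "date_diagnosis"),
    "ttt": ("date_presentation", "date_surgery"),
    "tdg": ("date_downgrade", "date_surgery"),
    "wait_time": ("date_diagnosis", "date_surgery"),
}


@dataclasses.dataclass(frozen=True)
class BinConfig:
    """Binning configuration: two tertile edges per pathway duration (months).

    A duration d maps to level 0 if d < lo, 1 if lo <= d < hi, else 2.
    """

    pathway_edges: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        unknown = set(self.pathway_edges) - set(PATHWAY_VARIABLES)
        if unknown:
            raise KeyError(f"unknown bin config keys: {sorted(unknown)}")
        missing = set(PATHWAY_VARIABLES) - set(self.pathway_edges)
        if missing:
            raise KeyError(f"bin config missing pathway variables: {sorted(missing)}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: list(v) for k, v in self.pathway_edges.items()}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BinConfig":
        raw = json.loads(Path(path).read_text())
        return cls({k: (float(v[0]), float(v[1])) for k, v in raw.items()})


def _months(df: pd.DataFrame, start: str, end: str) -> pd.Series:
    d0 = pd.to_datetime(df[start])
    d1 = pd.to_datetime(df[end])
    return (d1 - d0).dt.days / DAYS_PER_MONTH


def _validate_dates(df: pd.DataFrame) -> None:
    order = ["date_onset", "date_presentation", "date_diagnosis", "date_surgery"]
    dates = {c: pd.to_datetime(df[c]) for c in order + ["date_downgrade"]}
    for a, b in zip(order, order[1:]):
        if (dates[a] > dates[b]).any():
            raise ValueError(f"date ordering violated: {a} > {b}")
    if (dates["date_downgrade"] > dates["date_surgery"]).any():
        raise ValueError("date ordering violated: date_downgrade > date_surgery")


def make_bin_config(raw: pd.DataFrame) -> BinConfig:
    """Tertile pathway-duration edges computed from a raw cohort."""
    edges = {}
    for name, (start, end) in PATHWAY_VARIABLES.items():
        m = _months(raw, start, end)
        lo, hi = np.nanpercentile(m, [100 / 3, 200 / 3])
        edges[name] = (float(lo), float(hi))
    return BinConfig(edges)


# --- individual grouping rules -------------------------------------------
# Bin edges are half-open on the side the guideline states; terminal bins
# absorb the rest.  NaN inputs (FAAM/EILP only) propagate to NaN groups.

def _cut(values: pd.Series, edges: Iterable[float], right_closed: bool = False
         ) -> pd.Series:
    """Map values to 0..len(edges) by threshold; NaN stays NaN."""
    v = values.astype(float)
    out = pd.Series(np.zeros(len(v)), index=v.index)
    for e in edges:
        out = out + ((v > e) if right_closed else (v >= e)).astype(int)
    out[v.isna()] = np.nan
    return out


def _smoking_group(cigs: pd.Series) -> pd.Series:
    v = cigs.astype(float)
    out = pd.Series(np.zeros(len(v)), index=v.index)
    out[(v > 0) & (v < 10)] = 1  # light
    out[(v >= 10) & (v <= 20)] = 2  # moderate
    out[v > 20] = 3  # heavy
    return out


def _bp_overall(sys: pd.Series, dia: pd.Series) -> pd.Series:
    # AHA 2017: Normal / Elevated / Stage 1 / Stage 2; overall = worse of two.
    s, d = sys.astype(float), dia.astype(float)
    out = pd.Series(np.zeros(len(s)), index=s.index)
    out[(s >= 120) & (s < 130) & (d < 80)] = 1
    out[((s >= 130) & (s < 140)) | ((d >= 80) & (d < 90))] = 2
    out[(s >= 140) | (d >= 90)] = 3
    return out


def derive_features(raw: pd.DataFrame, bin_config: BinConfig | None = None
                    ) -> pd.DataFrame:
    """Derive the processed 23-feature matrix (plus ``outcome``) from raw rows.

    Row-wise apart from the pathway tertile edges, which come from
    ``bin_config`` (default: tertiles of this cohort via
    :func:`make_bin_config`).  Missing FAAM/EILP yield NaN groups for
    :func:`impute_missing` to fill.
    """
    _validate_dates(raw)
    if (raw[["height", "weight", "bp_systolic", "bp_diastolic"]] <= 0).any().any():
        raise ValueError("heights, weights and blood pressures must be positive")
    if bin_config is None:
        bin_config = make_bin_config(raw)

    bmi = raw["weight"] / (raw["height"] / 100.0) ** 2
    map_ = (raw["bp_systolic"] + 2 * raw["bp_diastolic"]) / 3.0

    out = pd.DataFrame(index=raw.index)
    out["age_group"] = _cut(raw["age"], [25, 30], right_closed=True)
    out["rank_group"] = np.minimum(raw["job_rank"].astype(int), 2)
    out["height_group"] = _cut(raw["height"], [170, 180])
    out["weight_group"] = _cut(raw["weight"], [75, 85, 95])
    out["bmi_group"] = _cut(bmi, [18.5, 25, 30])
    out["bp_systolic_group"] = _cut(raw["bp_systolic"], [120, 130, 140])
    out["bp_diastolic_group"] = _cut(raw["bp_diastolic"], [80, 90])
    out["bp_overall_group"] = _bp_overall(raw["bp_systolic"], raw["bp_diastolic"])
    out["map_group"] = _cut(map_, [60, 100])
    out["smoking_group"] = _smoking_group(raw["cigarettes_per_day"])
    out["alcohol_group"] = _cut(raw["alcohol_units_per_week"], [14], right_closed=True)
    out["faam_group"] = _cut(raw["faam"], [20, 40, 60, 80])
    out["eilp_group"] = _cut(raw["eilp"], [20, 40, 60, 80])
    for name, (start, end) in PATHWAY_VARIABLES.items():
        m = _months(raw, start, end)
        lo, hi = bin_config.pathway_edges[name]
        out[f"{name}_group"] = _cut(m, [lo, hi])
    for flag in ("prior_injury", "prior_surgery", "prior_inpatient_rehab",
                 "comorbidity"):
        out[flag] = (raw[flag].astype(float) > 0).astype(int)
    out["outcome"] = raw["outcome"].astype(int)
    return out[PROCESSED_FEATURES + ["outcome"]]


_IMPUTABLE = ("faam_group", "eilp_group")


def impute_missing(matrix: pd.DataFrame, mode: str = "faithful",
                   train_index: np.ndarray | None = None) -> pd.DataFrame:
    """Group-level median imputation of missing FAAM/EILP groups.

    ``faithful`` replicates the original procedure: the median of the
    record's outcome group over the full matrix.  ``hygienic`` restricts
    median computation to ``train_index`` rows; rows outside the training
    index (whose outcome must be treated as unknown) receive the training
    rows' overall median instead.
    """
    other = [c for c in PROCESSED_FEATURES if c not in _IMPUTABLE]
    if matrix[other].isna().any().any():
        bad = [c for c in other if matrix[c].isna().any()]
        raise ValueError(f"missing values outside FAAM/EILP groups: {bad}")
    if mode not in ("faithful", "hygienic"):
        raise ValueError(f"unknown imputation mode: {mode!r}")
    if mode == "hygienic" and train_index is None:
        raise ValueError("hygienic mode requires train_index")

    out = matrix.copy()
    ref = out if mode == "faithful" else out.loc[train_index]
    for col in _IMPUTABLE:
        if not out[col].isna().any():
            continue
        group_median = ref.groupby("outcome")[col].median()
        overall_median = ref[col].median()
        miss = out[col].isna()
        if mode == "hygienic":
            in_train = out.index.isin(np.asarray(train_index))
            fill = out["outcome"].map(group_median).where(in_train, overall_median)
        else:
            fill = out["outcome"].map(group_median)
        # medians of even-sized groups can fall between levels; round back
        # onto the declared level set
        out.loc[miss, col] = np.round(fill[miss].astype(float))
    return out


@dataclasses.dataclass(frozen=True)
class OutlierReport:
    scores: np.ndarray
    threshold: float
    removed_ids: list

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "scores": [float(s) for s in self.scores],
            "threshold": float(self.threshold),
            "removed_ids": [int(i) for i in self.removed_ids],
        }, indent=2))


_DISTANCE_FLOOR = 1e-12


def raw_outlier_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Numeric view of a raw cohort for outlier scoring.

    Continuous/count fields plus the six pathway durations in months;
    missing FAAM/EILP are filled with the column median for scoring only
    (they stay missing in the cohort itself).
    """
    cols = ["age", "job_rank", "height", "weight", "bp_systolic",
            "bp_diastolic", "cigarettes_per_day", "alcohol_units_per_week",
            "faam", "eilp"]
    frame = raw[cols].astype(float).copy()
    for name, (start, end) in PATHWAY_VARIABLES.items():
        frame[name] = _months(raw, start, end)
    return frame.fillna(frame.median())


def outlier_scores(matrix: pd.DataFrame, k: int = 10) -> np.ndarray:
    """Relative-density outlier score per record.

    On min-max-normalised features, density = 1 / mean Euclidean distance
    to the k nearest neighbours (floored at 1e-12 so duplicated records
    score 1); score = mean neighbour density / own density.  Scores near 1
    mean the record sits in a region of uniform density; scores far above
    1 mean it is isolated relative to its neighbourhood.  Accepts any
    numeric feature matrix (an ``outcome`` column, if present, is ignored).
    """
    feats = [c for c in matrix.columns if c != "outcome"]
    X = matrix[feats].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("outlier scoring requires a complete matrix")
    n = X.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} records for k={k}")
    rng_ = X.max(axis=0) - X.min(axis=0)
    rng_[rng_ == 0] = 1.0
    Xn = (X - X.min(axis=0)) / rng_
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xn)
    dist, idx = nn.kneighbors(Xn)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    mean_dist = np.maximum(dist.mean(axis=1), _DISTANCE_FLOOR)
    density = 1.0 / mean_dist
    neighbour_density = density[idx].mean(axis=1)
    return neighbour_density / density


def remove_outliers(matrix: pd.DataFrame, k: int = 10
                    ) -> tuple[pd.DataFrame, OutlierReport]:
    """Drop records whose score exceeds Q3 + 1.5 IQR (strict inequality)."""
    scores = outlier_scores(matrix, k=k)
    q1, q3 = np.percentile(scores, [25, 75])
    threshold = q3 + 1.5 * (q3 - q1)
    removed = scores > threshold
    report = OutlierReport(
        scores=scores,
        threshold=float(threshold),
        removed_ids=list(matrix.index[removed]),
    )
    return matrix.loc[~removed], report


def preprocess_cohort(raw: pd.DataFrame, bin_config: BinConfig | None = None,
                      imputation_mode: str = "faithful",
                      drop_outliers: bool = True, k: int = 10
                      ) -> tuple[pd.DataFrame, OutlierReport | None]:
    """Full preprocessing: remove outliers -> derive features -> impute.

    Outlier scoring runs on the min-max-normalised raw numeric fields
    (plus pathway durations) before any grouping, so genuinely extreme
    values are still visible to the detector; pathway-tertile bin edges
    are then computed on the surviving rows.  In ``hygienic`` mode
    imputation is deferred to the cross-validation loop and the returned
    matrix keeps its missing FAAM/EILP groups.
    """
    report: OutlierReport | None = None
    if drop_outliers:
        scores = outlier_scores(raw_outlier_features(raw), k=k)
        q1, q3 = np.percentile(scores, [25, 75])
        threshold = q3 + 1.5 * (q3 - q1)
        removed = scores > threshold
        report = OutlierReport(scores=scores, threshold=float(threshold),
                               removed_ids=list(raw.index[removed]))
        raw = raw.loc[~removed]
    matrix = derive_features(raw, bin_config)
    if imputation_mode == "faithful":
        matrix = impute_missing(matrix, mode="faithful")
    return matrix, report
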