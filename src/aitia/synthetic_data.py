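"""Synthetic cohorts and overlap benchmarks.

The study cohort behind this package — per-surgery clinical records of
military personnel undergoing fasciotomy for chronic exertional compartment
syndrome (CECS), labelled by return to full deployability within one year —
is not publicly deposited.  This module generates cohorts that follow the
same raw schema (demographics, blood pressure, lifestyle, FAAM/EILP
questionnaire scores, pathway dates, prior-history flags) with a single
``overlap`` knob controlling how separable the two outcome groups are, so
that every downstream stage (preprocessing, statistics, feature selection,
evaluation, interrogation) can be exercised and its behaviour checked
against known ground truth.

Raw features are drawn from outcome-conditional distributions: continuous
fields through latent Gaussians whose class-conditional means are pulled
apart by ``1 - overlap``, binary flags through outcome-dependent Bernoulli
rates interpolated the same way.  Pathway dates are built from an onset
date plus exponential waiting times (months), so the six derived durations
(chronicity, TTP, TTD, TTT, TDG, wait time) are co-linear by construction,
mirroring the strong duration correlations seen in real referral pathways.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSpec",
    "OverlapBenchmark",
    "RAW_COLUMNS",
    "generate_raw_cohort",
    "generate_overlap_benchmark",
    "write_cohort_csv",
]

#: Column order of the raw cohort table (predictors then outcome).
RAW_COLUMNS = [
    "age",
    "job_rank",
    "height",
    "weight",
    "bp_systolic",
    "bp_diastolic",
    "cigarettes_per_day",
    "alcohol_units_per_week",
    "faam",
    "eilp",
    "date_onset",
    "date_presentation",
    "date_diagnosis",
    "date_downgrade",
    "date_surgery",
    "prior_injury",
    "prior_surgery",
    "prior_inpatient_rehab",
    "comorbidity",
    "surgeon_id",
    "outcome",
]

# Continuous raw fields eligible for outlier injection.
_NUMERIC_FIELDS = [
    "height",
    "weight",
    "bp_systolic",
    "bp_diastolic",
    "cigarettes_per_day",
    "alcohol_units_per_week",
]

# Maximum latent mean separation (in latent SD units) at overlap = 0.
_MAX_SEPARATION = 6.0


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic raw cohort.

    Defaults reproduce the study conditions: 126 records with a 29/97
    good/poor outcome split (minority fraction 29/126), ~20% missingness in
    the FAAM/EILP questionnaire scores, and no injected outliers.
    """

    n_records: int = 126
    minority_fraction: float = 29 / 126
    overlap: float = 0.5
    outlier_rate: float = 0.0
    missing_rate_faam_eilp: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if not 0.0 < self.minority_fraction < 1.0:
            raise ValueError("minority_fraction must lie in (0, 1)")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
        if not 0.0 <= self.outlier_rate <= 0.2:
            raise ValueError("outlier_rate must lie in [0, 0.2]")
        if not 0.0 <= self.missing_rate_faam_eilp <= 0.5:
            raise ValueError("missing_rate_faam_eilp must lie in [0, 0.5]")

    @property
    def n_minority(self) -> int:
        return int(round(self.minority_fraction * self.n_records))


@dataclasses.dataclass(frozen=True)
class OverlapBenchmark:
    """Two-class Gaussian-mixture sample with known posterior.

    ``true_posterior[i]`` is the probability, under the generating mixture,
    that point ``i`` belongs to its own class.
    """

    points: np.ndarray
    labels: np.ndarray
    true_posterior: np.ndarray


#: Loading of each feature on the shared severity latent.  Features are
#: noisy reflections of one underlying severity, so the class-conditional
#: joint separation is governed by the latent's mean gap alone and the
#: overlap knob has a smooth effect on downstream difficulty.
_LOADING = 0.6


def _severity(rng: np.random.Generator, outcome: np.ndarray, overlap: float
              ) -> np.ndarray:
    """Shared severity latent: N(+-d/2, 1) by outcome class.

    Good outcomes (label 1) sit at +d/2, poor at -d/2, with
    d = _MAX_SEPARATION * (1 - overlap).
    """
    d = _MAX_SEPARATION * (1.0 - overlap)
    return d * (outcome - 0.5) + rng.standard_normal(outcome.shape[0])


def _feature_latent(rng: np.random.Generator, severity: np.ndarray,
                    sign: float = 1.0) -> np.ndarray:
    """Unit-variance feature latent loaded on the shared severity."""
    eps = rng.standard_normal(severity.shape[0])
    return sign * _LOADING * severity + np.sqrt(1 - _LOADING**2) * eps


def _flag(rng: np.random.Generator, outcome: np.ndarray, overlap: float,
          p_poor: float, p_good: float) -> np.ndarray:
    """Outcome-dependent Bernoulli flag; rates converge as overlap -> 1."""
    mid = 0.5 * (p_poor + p_good)
    p0 = mid + (1.0 - overlap) * (p_poor - mid)
    p1 = mid + (1.0 - overlap) * (p_good - mid)
    p = np.where(outcome == 1, p1, p0)
    return (rng.random(outcome.shape[0]) < p).astype(int)


def generate_raw_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a raw-schema cohort table.

    Returns a DataFrame with the :data:`RAW_COLUMNS` schema: dates as
    ISO-8601 strings, flags as 0/1 integers, ``outcome`` 1 = good
    (returned to full deployability within a year), 0 = poor.  FAAM/EILP
    are set missing at ``spec.missing_rate_faam_eilp``; ``spec.outlier_rate``
    of the rows have 3-5 numeric fields pushed to 4x beyond the observed
    range to give the relative-density outlier detector planted positives.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    n_min = spec.n_minority
    if not 0 < n_min < n:
        raise ValueError("minority_fraction yields an empty class")

    outcome = np.zeros(n, dtype=int)
    outcome[rng.choice(n, size=n_min, replace=False)] = 1
    ov = spec.overlap

    u = _severity(rng, outcome, ov)

    # Demographics / physiology.  Good outcomes (high severity latent) skew
    # younger, taller, lighter and with lower blood pressure, matching the
    # direction of the between-group differences the framework must detect.
    age = np.clip(27 + 4 * _feature_latent(rng, u, sign=-1.0), 18, 55)
    height = np.clip(176 + 7 * _feature_latent(rng, u, sign=1.0), 150, 205)
    weight = np.clip(82 + 10 * _feature_latent(rng, u, sign=-1.0), 50, 140)
    bp_sys = np.clip(124 + 12 * _feature_latent(rng, u, sign=-1.0), 90, 200)
    bp_dia = np.clip(78 + 9 * _feature_latent(rng, u, sign=-1.0), 50, 130)
    job_rank = np.clip(
        np.floor(1.2 + 0.9 * _feature_latent(rng, u, sign=-1.0)), 0, 5
    ).astype(int)

    # Lifestyle: counts via rounded, clipped latents.
    cigs = np.clip(np.round(6 + 8 * _feature_latent(rng, u, sign=-1.0)), 0, 60)
    units = np.clip(np.round(10 + 7 * _feature_latent(rng, u, sign=-1.0)), 0, 80)

    # Questionnaire percent scores: good outcomes score higher (less affected).
    faam = np.clip(55 + 18 * _feature_latent(rng, u, sign=1.0), 0, 100)
    eilp = np.clip(48 + 18 * _feature_latent(rng, u, sign=1.0), 0, 100)

    # Pathway dates: onset + exponential waits in months, log-scaled by the
    # severity latent so poor outcomes wait longer.  TTT = TTD + wait by
    # construction, giving the co-linear duration block.
    onset = pd.Timestamp("2015-01-01") + pd.to_timedelta(
        rng.integers(0, 4 * 365, size=n), unit="D"
    )
    scale = np.exp(-0.35 * _LOADING * u)  # >1 for poor outcomes
    ttp_m = rng.exponential(4.0, n) * scale
    ttd_m = rng.exponential(6.0, n) * scale
    wait_m = rng.exponential(5.0, n) * scale
    dgl_m = rng.exponential(3.0, n)  # downgrade lag after presentation

    def _days(months: np.ndarray) -> np.ndarray:
        return np.round(months * 30.44).astype(int)

    ttp_d, ttd_d, wait_d = _days(ttp_m), _days(ttd_m), _days(wait_m)
    dgl_d = np.minimum(_days(dgl_m), ttd_d + wait_d)  # downgrade <= surgery
    presentation = onset + pd.to_timedelta(ttp_d, unit="D")
    diagnosis = presentation + pd.to_timedelta(ttd_d, unit="D")
    surgery = diagnosis + pd.to_timedelta(wait_d, unit="D")
    downgrade = presentation + pd.to_timedelta(dgl_d, unit="D")

    df = pd.DataFrame(
        {
            "age": np.round(age, 1),
            "job_rank": job_rank,
            "height": np.round(height, 1),
            "weight": np.round(weight, 1),
            "bp_systolic": np.round(bp_sys).astype(int),
            "bp_diastolic": np.round(bp_dia).astype(int),
            "cigarettes_per_day": cigs.astype(int),
            "alcohol_units_per_week": units.astype(int),
            "faam": np.round(faam, 1),
            "eilp": np.round(eilp, 1),
            "date_onset": onset.strftime("%Y-%m-%d"),
            "date_presentation": presentation.strftime("%Y-%m-%d"),
            "date_diagnosis": diagnosis.strftime("%Y-%m-%d"),
            "date_downgrade": downgrade.strftime("%Y-%m-%d"),
            "date_surgery": surgery.strftime("%Y-%m-%d"),
            "prior_injury": _flag(rng, outcome, ov, 0.55, 0.35),
            "prior_surgery": _flag(rng, outcome, ov, 0.30, 0.10),
            "prior_inpatient_rehab": _flag(rng, outcome, ov, 0.45, 0.20),
            "comorbidity": _flag(rng, outcome, ov, 0.35, 0.20),
            "surgeon_id": rng.integers(1, 6, size=n),
            "outcome": outcome,
        }
    )

    # Missingness in the questionnaire scores only (MCAR).
    for col in ("faam", "eilp"):
        miss = rng.random(n) < spec.missing_rate_faam_eilp
        df.loc[miss, col] = np.nan

    # Outlier injection: push 3-5 numeric fields of each chosen row to 4x
    # beyond the currently observed range.
    n_out = int(round(spec.outlier_rate * n))
    if n_out:
        rows = rng.choice(n, size=n_out, replace=False)
        for r in rows:
            fields = rng.choice(
                _NUMERIC_FIELDS, size=int(rng.integers(3, 6)), replace=False
            )
            for f in fields:
                hi = df[f].max()
                df.loc[r, f] = 4.0 * hi
    return df


def generate_overlap_benchmark(
    n: int, overlap: float, seed: int, dim: int = 1
) -> OverlapBenchmark:
    """Two-class truncated-Gaussian mixture with known per-point posterior.

    Each class is an isotropic Gaussian truncated at 4 SD, classes centred
    at +-d/2 along the first axis with d = 8*(1-overlap); supports are
    therefore disjoint at overlap = 0 and coincide at overlap = 1.
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    d = 8.0 * (1.0 - overlap)
    labels = (rng.random(n) < 0.5).astype(int)
    trunc = stats.truncnorm(-4.0, 4.0)
    noise = trunc.rvs(size=(n, dim), random_state=rng)
    centres = np.zeros((n, dim))
    centres[:, 0] = d * (labels - 0.5)
    points = centres + noise

    # Posterior of the point's own class under equal priors; densities
    # factorise so only the first axis differs between classes.
    x0 = points[:, 0]
    f1 = trunc.pdf(x0 - d / 2)
    f0 = trunc.pdf(x0 + d / 2)
    denom = f0 + f1
    own = np.where(labels == 1, f1, f0)
    # Outside the rival support one density is 0; denom > 0 always holds
    # because every point lies inside its own class's support.
    posterior = own / denom
    return OverlapBenchmark(points=points, labels=labels, true_posterior=posterior)


def write_cohort_csv(df: pd.DataFrame, path: str | Path,
                     spec: CohortSpec | None = None) -> None:
    """Write a raw cohort to CSV; optional JSON sidecar records the spec."""
    path = Path(path)
    df.to_csv(path, index=False, columns=RAW_COLUMNS)
    if spec is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(dataclasses.asdict(spec), indent=2))


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path)
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"raw cohort is missing columns: {sorted(missing)}")
    return df[RAW_COLUMNS]
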