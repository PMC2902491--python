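"""Daily symptom-diary scoring and Sunday-to-Saturday weekly aggregation.

Six lower-respiratory-tract (LRT) symptoms are each rated daily on a
0 (none) to 4 (very severe) scale; the daily LRT score is their sum
(0-24), treated as missing whenever any component is missing.  Daily
scores are aggregated into weekly averages over Sunday-Saturday windows
covering the 2004 study year: week 1 starts Sunday 2004-01-04 and week 51
is the last complete week.  A weekly average is the mean of the observed
days when at most two of the seven days are missing, and missing
otherwise.  (Imputing a missing day by the weekly average leaves the mean
unchanged, so "impute then average" and "average the observed days" are
the same rule.)  Week-level viral status is positive if any day of the
week is flagged positive.

Because the cohort data itself is not public, a synthetic diary generator
with the same shape (about 75% zero weekly scores, right-skewed positive
scores, a rare viral-week flag, seasonal trend, heterogeneous subjects)
is provided so the full aggregate-then-fit pipeline can be exercised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .skewnormal import SkewNormalParams, sn_rvs

__all__ = [
    "SYMPTOM_COLUMNS",
    "WEEK1_SUNDAY",
    "daily_lrt_score",
    "weekly_average",
    "calendarize",
    "aggregate_diary",
    "synthesize_diary",
]

SYMPTOM_COLUMNS = [
    "cough_day",
    "cough_night",
    "wheeze",
    "breath_day",
    "breath_night",
    "activity_limit",
]
WEEK1_SUNDAY = pd.Timestamp("2004-01-04")
N_WEEKS = 51


def daily_lrt_score(scores) -> float:
    """Daily LRT total: sum of the six symptom ratings, in [0, 24].

    Missing if any component is missing; ratings outside {0..4} raise.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.shape != (6,):
        raise ValueError(f"expected six symptom scores, got shape {arr.shape}")
    present = ~np.isnan(arr)
    vals = arr[present]
    if np.any((vals < 0) | (vals > 4) | (vals != np.round(vals))):
        raise ValueError("symptom scores must be integers in 0..4 (or missing)")
    if not present.all():
        return float("nan")
    return float(arr.sum())


def weekly_average(daily_scores) -> float:
    """Weekly average LRT score from up to 7 daily values (NaN = missing).

    Days not supplied count as missing; more than two missing days in the
    Sunday-Saturday window make the weekly value missing, otherwise the
    mean of the observed days is returned.
    """
    arr = np.asarray(daily_scores, dtype=float)
    if arr.ndim != 1 or arr.size > 7:
        raise ValueError(f"expected at most 7 daily values, got shape {arr.shape}")
    obs = arr[~np.isnan(arr)]
    n_missing = 7 - obs.size
    if n_missing > 2:
        return float("nan")
    return float(obs.mean())


def calendarize(dates):
    """Map dates to study week indices 1..51 (Sunday-Saturday windows).

    Week 1 starts Sunday 2004-01-04.  Dates before that, or past the end
    of week 51, get a missing (<NA>) marker.
    """
    d = pd.to_datetime(pd.Series(np.atleast_1d(np.asarray(dates, dtype=object))))
    week = ((d - WEEK1_SUNDAY).dt.days // 7 + 1).astype("Int64")
    week[(week < 1) | (week > N_WEEKS)] = pd.NA
    if np.ndim(dates) == 0 and not isinstance(dates, (list, tuple, pd.Series, np.ndarray)):
        return week.iloc[0]
    return week.to_numpy()


def aggregate_diary(
    diary: pd.DataFrame,
    subject_col: str = "subject_id",
    date_col: str = "date",
    symptom_cols=SYMPTOM_COLUMNS,
    viral_col: str | None = "viral",
    covariate_cols=("asthma", "male", "age"),
    drop_missing: bool = True,
) -> pd.DataFrame:
    """Aggregate a daily diary into the weekly long format used for fitting.

    Returns columns ``subject``, ``week``, ``y`` (weekly average LRT
    score), the week-level viral flag (any positive day), and one row of
    subject covariates.  Weeks with more than two missing daily scores are
    missing and dropped unless ``drop_missing=False``.
    """
    for col in [subject_col, date_col, *symptom_cols]:
        if col not in diary.columns:
            raise KeyError(f"column {col!r} not found in diary")
    covariate_cols = [c for c in covariate_cols if c in diary.columns]

    df = diary.copy()
    sym = df[list(symptom_cols)].to_numpy(dtype=float)
    ok = ~np.isnan(sym)
    vals = sym[ok]
    if np.any((vals < 0) | (vals > 4) | (vals != np.round(vals))):
        raise ValueError("symptom scores must be integers in 0..4 (or missing)")
    daily = np.where(ok.all(axis=1), np.nansum(sym, axis=1), np.nan)
    df["_daily"] = daily
    df["week"] = calendarize(df[date_col].to_numpy())
    df = df[df["week"].notna()].copy()
    df["week"] = df["week"].astype(int)

    def _week(group: pd.DataFrame) -> pd.Series:
        out = {"y": weekly_average(group["_daily"].to_numpy())}
        if viral_col and viral_col in group:
            v = group[viral_col].fillna(0).to_numpy(dtype=float)
            out["viral"] = float((v > 0).any())
        return pd.Series(out)

    weekly = (
        df.groupby([subject_col, "week"], sort=True)
        .apply(_week, include_groups=False)
        .reset_index()
        .rename(columns={subject_col: "subject"})
    )
    if covariate_cols:
        cov = (
            df.groupby(subject_col, sort=True)[covariate_cols]
            .first()
            .reset_index()
            .rename(columns={subject_col: "subject"})
        )
        weekly = weekly.merge(cov, on="subject", how="left")
    if drop_missing:
        weekly = weekly[weekly["y"].notna()].reset_index(drop=True)
    return weekly


def synthesize_diary(
    n_subjects: int = 190,
    n_weeks: int = N_WEEKS,
    asthma_fraction: float = 135 / 190,
    baseline_zero_prob: float = 0.75,
    viral_week_rate: float = 0.03,
    viral_effect_probit: float = 2.0,
    viral_effect_severity: float = 0.7,
    asthma_effect_probit: float = 0.5,
    seasonal_amplitude: float = 0.3,
    severity_mu: float = 0.5,
    sigma: float = 0.6,
    delta: float = -0.8,
    s11: float = 1.0,
    s22: float = 0.2,
    s12: float = 0.2,
    missing_day_rate: float = 0.02,
    seed=None,
) -> pd.DataFrame:
    """Synthetic daily diary with cohort-like weekly structure.

    A week is symptomatic with probit probability
    ``Phi(z0 + asthma and viral effects + seasonal trend + tau0)`` where
    ``z0 = Phi^{-1}(1 - baseline_zero_prob) * sqrt(1 + s11)`` so the
    *marginal* zero-week fraction equals ``baseline_zero_prob`` when the
    effects are zero.  Symptomatic weeks get a log-skew-normal weekly mean
    severity; daily totals are Poisson draws around it (capped at 24, at
    least one positive day) split over the six symptoms by capacity-capped
    urn draws, so every daily panel is a valid set of 0-4 ratings.  Days
    go missing completely at random at ``missing_day_rate``.

    The generator emulates the zero-inflation, skew, rare viral weeks,
    seasonality and subject heterogeneity of the cohort; it makes no
    attempt to clone unpublished raw-diary noise (its job is pipeline
    testing and effect-direction recovery).
    """
    if not (0.0 < baseline_zero_prob < 1.0):
        raise ValueError("baseline_zero_prob must be in (0, 1)")
    if s11 < 0 or s22 < 0 or s11 * s22 < s12**2:
        raise ValueError("random-effects covariance must be positive semidefinite")
    rng = np.random.default_rng(seed)
    asthma = (rng.random(n_subjects) < asthma_fraction).astype(int)
    male = (rng.random(n_subjects) < 0.5).astype(int)
    age = rng.integers(5, 12, size=n_subjects)
    if s11 > 0 and s22 > 0:
        L = np.linalg.cholesky(np.array([[s11, s12], [s12, s22]]) + 1e-12 * np.eye(2))
        tau = rng.standard_normal((n_subjects, 2)) @ L.T
    else:
        tau = np.zeros((n_subjects, 2))

    z0 = ndtri(1.0 - baseline_zero_prob) * np.sqrt(1.0 + s11)
    weeks = np.arange(1, n_weeks + 1)
    seasonal = seasonal_amplitude * np.cos(2.0 * np.pi * (weeks - 1) / n_weeks)

    viral = rng.random((n_subjects, n_weeks)) < viral_week_rate
    eta = (
        z0
        + asthma_effect_probit * asthma[:, None]
        + viral_effect_probit * viral
        + seasonal[None, :]
        + tau[:, [0]]
    )
    symptomatic = rng.random((n_subjects, n_weeks)) < ndtr(eta)
    mu_sev = severity_mu + viral_effect_severity * viral + tau[:, [1]]
    log_m = mu_sev + sn_rvs(
        SkewNormalParams(0.0, sigma, delta), n_subjects * n_weeks, rng
    ).reshape(n_subjects, n_weeks)
    m = np.clip(np.exp(log_m), 1e-3, 24.0)

    rows = []
    caps = np.array([4] * 6)
    for i in range(n_subjects):
        for wk in range(n_weeks):
            date0 = WEEK1_SUNDAY + pd.Timedelta(days=7 * wk)
            if symptomatic[i, wk]:
                totals = np.minimum(rng.poisson(m[i, wk], size=7), 24)
                if not totals.any():
                    totals[rng.integers(7)] = max(1, int(round(m[i, wk])))
            else:
                totals = np.zeros(7, dtype=int)
            viral_days = np.zeros(7, dtype=int)
            if viral[i, wk]:
                viral_days[rng.choice(7, size=rng.integers(1, 4), replace=False)] = 1
            missing = rng.random(7) < missing_day_rate
            for d in range(7):
                if missing[d]:
                    scores = [np.nan] * 6
                else:
                    scores = rng.multivariate_hypergeometric(caps, int(totals[d])).tolist()
                rows.append(
                    [i + 1, date0 + pd.Timedelta(days=d), *scores, int(viral_days[d]),
                     int(asthma[i]), int(male[i]), int(age[i])]
                )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "date", *SYMPTOM_COLUMNS, "viral", "asthma", "male", "age"],
    )
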