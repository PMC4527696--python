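"""Rotarod and grip-strength phenotype analysis.

Summaries follow the testing protocol: per day the best of three attempts is
kept and the five daily bests are averaged into one score per animal (ceiling
120 s); grip is a pass if any day's 30 s hold succeeded.  On the scores the
module provides Tukey five-number box summaries, least-squares regression on
sex/genotype/age covariates, the percentile-wise association between motor
performance and somatic repeat length, and operational onset-of-decline
detection against a wild-type reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    CoverageError,
    DesignError,
    InsufficientDataError,
    MissingDataError,
)
from .instability import PERCENTILES, quantile_values
from .peakfit import SomaticChangeDistribution

log = logging.getLogger(__name__)

FEWER_BETTER = "fewer-repeats-better"
MORE_WORSE = "more-repeats-worse"
NO_ASSOCIATION = "none"


@dataclass
class AnimalPerformance:
    """Protocol summary of one animal's rotarod and grip records."""

    animal_id: str
    speed_rpm: int
    best_daily_times: list[float]
    score: float
    grip_passed: bool

    def __post_init__(self):
        if not 0.0 <= self.score <= 120.0 + 1e-9:
            raise ValueError(f"score {self.score} outside [0, 120]")


@dataclass
class BoxSummary:
    """Tukey five-number summary of a group's scores."""

    group: str
    min: float
    q1: float
    median: float
    q3: float
    max: float

    def __post_init__(self):
        if not self.min <= self.q1 <= self.median <= self.q3 <= self.max:
            raise ValueError("box summary violates min<=q1<=median<=q3<=max")


def summarize_rotarod(records: pd.DataFrame, speed: int = 20) -> AnimalPerformance:
    """Best-of-3 per day, averaged over days, for one animal at one speed."""
    sub = records[records["speed_rpm"] == speed]
    if sub.empty:
        raise MissingDataError(f"no records at {speed} rpm")
    bests = sub.groupby("day")["time_s"].max()
    grip = bool(sub["grip_pass"].any()) if "grip_pass" in sub else False
    return AnimalPerformance(
        animal_id=str(records["animal_id"].iloc[0]),
        speed_rpm=speed,
        best_daily_times=bests.tolist(),
        score=float(bests.mean()),
        grip_passed=grip,
    )


def summarize_cohort(performance: pd.DataFrame, speed: int = 20) -> pd.DataFrame:
    """Per-animal scores and grip outcomes for a whole performance table."""
    rows = []
    for animal_id, sub in performance.groupby("animal_id", sort=False):
        perf = summarize_rotarod(sub, speed=speed)
        rows.append({"animal_id": animal_id, "score": perf.score,
                     "grip_passed": perf.grip_passed})
    return pd.DataFrame(rows)


def _tukey_hinges(values: np.ndarray) -> tuple[float, float, float]:
    x = np.sort(values)
    n = x.size
    m = (n + 1) // 2  # lower half includes the median when n is odd
    return (
        float(np.median(x[:m])),
        float(np.median(x)),
        float(np.median(x[n - m:])),
    )


def box_summary(scores: Sequence[float], group: str = "") -> BoxSummary:
    """Tukey five-number summary (hinges by median-of-halves); needs n >= 4."""
    values = np.asarray(list(scores), dtype=float)
    if values.size < 4:
        raise InsufficientDataError(f"box summary needs >= 4 scores, got {values.size}")
    q1, med, q3 = _tukey_hinges(values)
    return BoxSummary(group=group, min=float(values.min()), q1=q1,
                      median=med, q3=q3, max=float(values.max()))


def _covariate_matrix(df: pd.DataFrame, genotype_age_slopes: bool) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "female": (df["sex"] == "F").astype(float),
            "ogg1_ko": (df["ogg1_status"] == "-/-").astype(float),
            "hd_homo": (df["hd_zygosity"] == "Q150/Q150").astype(float),
            "age": df["age_weeks"].astype(float),
        }
    )
    if genotype_age_slopes:
        X["age_x_hd_homo"] = X["age"] * X["hd_homo"]
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name the aliased columns: those whose removal does not reduce rank
        aliased = [c for c in X.columns
                   if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank]
        raise DesignError(f"collinear design; aliased terms: {', '.join(aliased)}")


def performance_regression(
    df: pd.DataFrame, genotype_age_slopes: bool = False
) -> pd.DataFrame:
    """Least-squares fit of score on intercept + female + ogg1-KO + HD-homo + age.

    ``df`` needs columns ``score``, ``sex``, ``ogg1_status``, ``hd_zygosity``
    and ``age_weeks``.  With ``genotype_age_slopes`` an extra age × HD-homo
    slope is fitted.  Returns one row per term: estimate, SE, two-sided p.
    """
    X = _covariate_matrix(df, genotype_age_slopes)
    _check_rank(X)
    fit = sm.OLS(df["score"].to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()
    return pd.DataFrame(
        {"term": X.columns, "estimate": fit.params, "se": fit.bse, "p": fit.pvalues}
    ).reset_index(drop=True)


def quantile_performance_association(
    scores: pd.DataFrame,
    changes: Mapping[tuple[str, str], SomaticChangeDistribution],
    percentiles: Sequence[int] = PERCENTILES,
    tissues: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Percentile-wise association of motor score with somatic repeat length.

    For each (tissue, percentile) every animal contributes the Δ value at
    that percentile of its *own* distribution; the score is regressed on this
    value adjusted for HD genotype, OGG1 genotype, age and sex.  The slope
    sign is mapped to the reading of the published table: a negative slope
    (more repeats, less time on the rod) is labelled
    ``fewer-repeats-better`` in the lower half of the distribution and
    ``more-repeats-worse`` in the upper tail.  Animals lacking a tissue are
    excluded with a logged count.
    """
    if tissues is None:
        tissues = sorted({t for (_, t) in changes})
    rows = []
    for tissue in tissues:
        have = {a: changes[(a, tissue)] for (a, t) in changes if t == tissue}
        sub = scores[scores["animal_id"].isin(have)]
        n_missing = len(scores) - len(sub)
        if n_missing:
            log.info("tissue %s: excluded %d animals without a Δ distribution",
                     tissue, n_missing)
        if len(sub) < 10:
            raise InsufficientDataError(
                f"tissue {tissue!r}: only {len(sub)} animals with distributions"
            )
        per_animal_q = {
            a: quantile_values(have[a], percentiles) for a in sub["animal_id"]
        }
        X_cov = _covariate_matrix(sub, genotype_age_slopes=False)
        y = sub["score"].to_numpy(dtype=float)
        for p in percentiles:
            delta = np.array([per_animal_q[a][p] for a in sub["animal_id"]],
                             dtype=float)
            if np.ptp(delta) == 0:
                rows.append({"tissue": tissue, "percentile": p, "slope": 0.0,
                             "p": 1.0, "label": NO_ASSOCIATION, "n": len(sub)})
                continue
            X = np.column_stack([X_cov.to_numpy(dtype=float), delta])
            fit = sm.OLS(y, X).fit()
            slope, pval = float(fit.params[-1]), float(fit.pvalues[-1])
            if slope < 0 and pval <= alpha:
                label = FEWER_BETTER if p <= 50 else MORE_WORSE
            else:
                label = NO_ASSOCIATION
            rows.append({"tissue": tissue, "percentile": p, "slope": slope,
                         "p": pval, "label": label, "n": len(sub)})
    return pd.DataFrame(rows)


def _median(values) -> float:
    return float(np.median(np.asarray(list(values), dtype=float)))


def detect_onset(
    genotype_scores: Mapping[str, Sequence[float]],
    reference_scores: Mapping[str, Sequence[float]],
    margin: float | None = None,
    min_per_group: int = 5,
    min_groups: int = 3,
    group_order: Sequence[str] | None = None,
) -> str | None:
    """Earliest age group with a sustained motor deficit beyond the reference.

    Deficits are median differences from the wild-type reference, aligned at
    the first shared age group so that a genotype offset present from the
    youngest age does not register as decline.  Onset is the earliest later
    group whose aligned deficit exceeds ``margin`` (default: the Tukey IQR of
    the pooled reference scores) with the deficit persisting into the next
    group (vacuously true at the last group).  Returns the age-group label or
    ``None``.
    """
    if group_order is None:
        group_order = [g for g in genotype_scores]
    missing = [g for g in group_order if g not in reference_scores]
    if missing:
        raise CoverageError(f"reference missing for age group(s): {missing}")
    usable = [g for g in group_order
              if len(genotype_scores[g]) >= min_per_group
              and len(reference_scores[g]) >= min_per_group]
    if len(usable) < min_groups:
        raise InsufficientDataError(
            f"need >= {min_groups} age groups with >= {min_per_group} animals"
        )
    if margin is None:
        pooled = np.concatenate([np.asarray(reference_scores[g], dtype=float)
                                 for g in usable])
        q1, _, q3 = _tukey_hinges(pooled)
        margin = q3 - q1
    deficits = {
        g: (_median(reference_scores[g]) - _median(genotype_scores[g]))
        for g in usable
    }
    baseline = deficits[usable[0]]
    aligned = {g: deficits[g] - baseline for g in usable}
    for i, g in enumerate(usable[1:], start=1):
        if aligned[g] > margin:
            is_last = i == len(usable) - 1
            if is_last or aligned[usable[i + 1]] > margin:
                return g
    return None


def grip_pass_rate(passed: Sequence[bool]) -> float:
    """Percent of animals passing the grip test (any one success = pass)."""
    outcomes = list(passed)
    if not outcomes:
        raise InsufficientDataError("grip pass rate needs >= 1 animal")
    return 100.0 * sum(bool(x) for x in outcomes) / len(outcomes)
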