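"""Population-level statistics of somatic repeat change.

Per-animal Δ distributions are pooled (animal-equal-weight) into global
distributions per stratum, which are then compared between genotype groups at
fixed percentiles ("cells": 1st, 5th, ..., 99th) with animal-level bootstrap
standard errors, summarized by age window, and tested for zygosity/OGG1
interaction and for independence from the inherited allele size.

Percentiles use the weighted nearest-rank convention: the smallest Δ value on
the integer support whose cumulative frequency reaches the requested level.
Significance codes follow the convention * P≤0.05, † P≤0.01, ‡ P≤0.005.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import (
    DesignError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from .peakfit import SomaticChangeDistribution

#: the fixed percentile grid of the quantile-cell analysis
PERCENTILES = (1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 99)

#: age-window labels of the summary table mapped to age-group labels
SUMMARY_WINDOWS = {10: "5-10", 20: "11-20", 30: "21-30", 40: "31-40"}

_CODE_LEVELS = ((0.005, "‡"), (0.01, "†"), (0.05, "*"))  # ‡ † *


def significance_code(p: float) -> str:
    for level, code in _CODE_LEVELS:
        if p <= level:
            return code
    return ""


@dataclass
class GlobalDistribution:
    """Animal-equal-weight pooled Δ distribution for one stratum."""

    stratum: str
    frequencies: dict[int, float]
    n_animals: int

    def __post_init__(self):
        if self.n_animals < 1:
            raise InsufficientDataError("a global distribution needs >= 1 animal")
        total = sum(self.frequencies.values())
        self.frequencies = {
            int(k): v / total for k, v in sorted(self.frequencies.items()) if v > 0
        }

    @property
    def support(self) -> np.ndarray:
        return np.fromiter(self.frequencies.keys(), dtype=int)

    @property
    def probs(self) -> np.ndarray:
        return np.fromiter(self.frequencies.values(), dtype=float)

    def mean(self) -> float:
        return float(self.support @ self.probs)


@dataclass
class QuantileCell:
    """Between-group difference of one percentile of the pooled Δ law."""

    percentile: int
    value_g1: float
    value_g2: float
    difference: float
    se: float
    p: float
    code: str = field(init=False)

    def __post_init__(self):
        self.code = significance_code(self.p)


def pool_distributions(
    changes: Sequence[SomaticChangeDistribution],
    stratum: str = "",
    strata: Sequence | None = None,
) -> GlobalDistribution:
    """Pool per-animal Δ distributions with equal weight per animal.

    With ``strata`` (one label per animal, e.g. HD zygosity) the pooled law is
    the equal-weight average of the per-stratum pooled laws — the "combined
    and adjusted for zygosity" pooling used when both Q150 genotypes enter one
    comparison.
    """
    if not changes:
        raise InsufficientDataError(f"empty stratum {stratum!r}")
    if strata is not None:
        if len(strata) != len(changes):
            raise ValueError("strata must align with changes")
        freqs: dict[int, float] = {}
        labels = sorted(set(strata))
        for label in labels:
            sub = [c for c, s in zip(changes, strata) if s == label]
            pooled = pool_distributions(sub, stratum=str(label))
            for k, v in pooled.frequencies.items():
                freqs[k] = freqs.get(k, 0.0) + v / len(labels)
        return GlobalDistribution(stratum=stratum, frequencies=freqs,
                                  n_animals=len(changes))
    freqs = {}
    for c in changes:
        for k, v in c.frequencies.items():
            freqs[k] = freqs.get(k, 0.0) + v / len(changes)
    return GlobalDistribution(stratum=stratum, frequencies=freqs,
                              n_animals=len(changes))


def quantile_values(
    g: GlobalDistribution | SomaticChangeDistribution,
    percentiles: Iterable[int] = PERCENTILES,
) -> dict[int, int]:
    """Weighted nearest-rank percentiles of an integer-support distribution.

    The p-th percentile is the smallest support value whose cumulative
    frequency is >= p/100; values therefore stay on the integer Δ grid.
    """
    support = g.support
    cdf = np.cumsum(g.probs)
    out = {}
    for p in percentiles:
        idx = int(np.searchsorted(cdf, p / 100.0 - 1e-12))
        out[int(p)] = int(support[min(idx, support.size - 1)])
    return out


def _freq_matrix(
    changes: Sequence[SomaticChangeDistribution], support: np.ndarray
) -> np.ndarray:
    index = {int(s): i for i, s in enumerate(support)}
    F = np.zeros((len(changes), support.size))
    for row, c in enumerate(changes):
        for k, v in c.frequencies.items():
            F[row, index[int(k)]] = v
    return F


def _pooled_quantiles_rows(
    weights: np.ndarray, support: np.ndarray, percentiles: Sequence[int]
) -> np.ndarray:
    """Row-wise nearest-rank quantiles for a (draws x support) weight matrix."""
    cdf = np.cumsum(weights, axis=1)
    cdf /= cdf[:, -1:]
    out = np.empty((weights.shape[0], len(percentiles)))
    for j, p in enumerate(percentiles):
        idx = np.argmax(cdf >= p / 100.0 - 1e-12, axis=1)
        out[:, j] = support[idx]
    return out


def _stratified_boot_means(
    F: np.ndarray, strata: Sequence, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    labels = sorted(set(strata))
    strata = np.asarray(strata)
    acc = np.zeros((n_boot, F.shape[1]))
    for label in labels:
        rows = np.flatnonzero(strata == label)
        idx = rng.integers(0, rows.size, size=(n_boot, rows.size))
        acc += F[rows][idx].mean(axis=1) / len(labels)
    return acc


def cell_differences(
    g1_changes: Sequence[SomaticChangeDistribution],
    g2_changes: Sequence[SomaticChangeDistribution],
    percentiles: Sequence[int] = PERCENTILES,
    n_boot: int = 2000,
    seed: int = 0,
    strata1: Sequence | None = None,
    strata2: Sequence | None = None,
    min_animals: int = 5,
) -> list[QuantileCell]:
    """Per-percentile difference g1 − g2 with animal-bootstrap SE and p.

    Animals are resampled with replacement (within stratum when strata are
    given, preserving the equal-stratum-weight pooling); the SE is the
    bootstrap SD of the difference and the two-sided p-value is the
    (add-one-corrected) bootstrap sign probability.  Deterministic for a
    fixed seed and ``n_boot``.
    """
    if len(g1_changes) < min_animals or len(g2_changes) < min_animals:
        raise InsufficientDataError(
            f"need >= {min_animals} animals per group "
            f"(got {len(g1_changes)}, {len(g2_changes)})"
        )
    support = np.array(sorted(
        {k for c in list(g1_changes) + list(g2_changes) for k in c.frequencies}
    ))
    F1 = _freq_matrix(g1_changes, support)
    F2 = _freq_matrix(g2_changes, support)
    rng = np.random.default_rng(seed)

    def observed_weights(F, strata):
        if strata is None:
            return F.mean(axis=0)[None, :]
        return _stratified_boot_means_observed(F, strata)

    q1 = _pooled_quantiles_rows(observed_weights(F1, strata1), support, percentiles)[0]
    q2 = _pooled_quantiles_rows(observed_weights(F2, strata2), support, percentiles)[0]

    if strata1 is None:
        idx1 = rng.integers(0, F1.shape[0], size=(n_boot, F1.shape[0]))
        boot1 = F1[idx1].mean(axis=1)
    else:
        boot1 = _stratified_boot_means(F1, strata1, n_boot, rng)
    if strata2 is None:
        idx2 = rng.integers(0, F2.shape[0], size=(n_boot, F2.shape[0]))
        boot2 = F2[idx2].mean(axis=1)
    else:
        boot2 = _stratified_boot_means(F2, strata2, n_boot, rng)

    bq1 = _pooled_quantiles_rows(boot1, support, percentiles)
    bq2 = _pooled_quantiles_rows(boot2, support, percentiles)
    diffs = bq1 - bq2

    cells = []
    for j, p in enumerate(percentiles):
        d = diffs[:, j]
        se = float(d.std(ddof=1))
        n_le = int(np.sum(d <= 0)) + 1
        n_ge = int(np.sum(d >= 0)) + 1
        pval = min(1.0, 2.0 * min(n_le, n_ge) / (n_boot + 1))
        point = float(q1[j] - q2[j])
        if point == 0.0 and np.all(d == 0.0):
            pval = 1.0  # identical groups: no evidence of any difference
        cells.append(
            QuantileCell(percentile=int(p), value_g1=float(q1[j]),
                         value_g2=float(q2[j]), difference=point, se=se, p=pval)
        )
    return cells


def _stratified_boot_means_observed(F: np.ndarray, strata: Sequence) -> np.ndarray:
    labels = sorted(set(strata))
    strata = np.asarray(strata)
    acc = np.zeros((1, F.shape[1]))
    for label in labels:
        rows = np.flatnonzero(strata == label)
        acc += F[rows].mean(axis=0)[None, :] / len(labels)
    return acc


def cells_to_frame(cells: Sequence[QuantileCell], stratum: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum": stratum,
            "percentile": [c.percentile for c in cells],
            "value_g1": [c.value_g1 for c in cells],
            "value_g2": [c.value_g2 for c in cells],
            "difference": [c.difference for c in cells],
            "se": [c.se for c in cells],
            "p": [c.p for c in cells],
            "code": [c.code for c in cells],
        }
    )


# ---------------------------------------------------------------------------
# age-window summary and regression-style tests


def age_window_summary(
    df: pd.DataFrame,
    windows: Mapping[int, str] = SUMMARY_WINDOWS,
) -> pd.DataFrame:
    """Unadjusted mean ± SE of somatic change by age window and OGG1 status.

    ``df`` holds one row per (animal, tissue) with columns ``animal_id``,
    ``hd_zygosity``, ``ogg1_status``, ``age_group`` and ``mean_change``.  All
    brain regions are pooled by first averaging within animal; rows are
    produced for the combined Q150/Q150 + Q150/wt cohort and for Q150/Q150
    alone.  Empty windows yield a flagged row rather than a silent omission.
    """
    carriers = df[df["hd_zygosity"].isin(["Q150/Q150", "Q150/wt"])]
    per_animal = (
        carriers.groupby(
            ["animal_id", "hd_zygosity", "ogg1_status", "age_group"], as_index=False
        )["mean_change"].mean()
    )
    rows = []
    for cohort, sub in (
        ("combined", per_animal),
        ("homozygous", per_animal[per_animal["hd_zygosity"] == "Q150/Q150"]),
    ):
        for window, group_label in windows.items():
            for ogg1 in ("+/+", "-/-"):
                sel = sub[(sub["age_group"] == group_label)
                          & (sub["ogg1_status"] == ogg1)]
                n = len(sel)
                if n == 0:
                    rows.append({"cohort": cohort, "window": window,
                                 "ogg1_status": ogg1, "mean": np.nan, "se": np.nan,
                                 "n": 0, "flag": "empty"})
                    continue
                mean = float(sel["mean_change"].mean())
                se = float(sel["mean_change"].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
                rows.append({"cohort": cohort, "window": window,
                             "ogg1_status": ogg1, "mean": mean, "se": se,
                             "n": n, "flag": ""})
    return pd.DataFrame(rows)


def zygosity_interaction_test(df: pd.DataFrame) -> float:
    """P-value of the HD-zygosity × OGG1-status interaction on mean change.

    Fits an ordinary least-squares model of per-animal mean change on zygosity,
    OGG1 status and their interaction (carriers only) and returns the
    interaction p-value.
    """
    sub = df[df["hd_zygosity"].isin(["Q150/Q150", "Q150/wt"])].copy()
    if sub["hd_zygosity"].nunique() < 2 or sub["ogg1_status"].nunique() < 2:
        raise DesignError(
            "interaction test needs both zygosities and both OGG1 statuses"
        )
    sub["homo"] = (sub["hd_zygosity"] == "Q150/Q150").astype(float)
    sub["ko"] = (sub["ogg1_status"] == "-/-").astype(float)
    model = smf.ols("mean_change ~ homo * ko", data=sub).fit()
    return float(model.pvalues["homo:ko"])


def inherited_length_association(
    df: pd.DataFrame, min_animals: int = 10
) -> dict[str, float]:
    """Per-tissue p-value for inherited size → somatic change regression.

    ``df`` holds one row per (animal, tissue) with ``inherited_repeats`` and
    ``mean_change``.  Returns the slope p-value per tissue plus an ``"all"``
    entry where tissues are first averaged within animal.
    """
    out: dict[str, float] = {}
    per_animal = df.groupby(["animal_id", "inherited_repeats"], as_index=False)[
        "mean_change"
    ].mean()
    for tissue, sub in [(t, g) for t, g in df.groupby("tissue")] + [
        ("all", per_animal)
    ]:
        if len(sub) < min_animals:
            raise InsufficientDataError(
                f"tissue {tissue!r}: {len(sub)} animals < {min_animals}"
            )
        x = sub["inherited_repeats"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise UndefinedStatisticError(
                f"tissue {tissue!r}: inherited sizes are constant; slope undefined"
            )
        X = sm.add_constant(x)
        fit = sm.OLS(sub["mean_change"].to_numpy(dtype=float), X).fit()
        out[tissue] = float(fit.pvalues[1])
    return out


def two_sample_z(mean1: float, se1: float, mean2: float, se2: float) -> float:
    """Z = (mean1 − mean2) / sqrt(se1² + se2²)."""
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be >= 0")
    if se1 == 0 and se2 == 0:
        raise UndefinedStatisticError("both standard errors are zero")
    return (mean1 - mean2) / math.hypot(se1, se2)


def plot_quantile_cells(cells: Sequence[QuantileCell], ax=None, title: str = ""):
    """Bar plot of cell differences with 1-SE whiskers (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    xs = np.arange(len(cells))
    diffs = [c.difference for c in cells]
    ses = [c.se for c in cells]
    ax.bar(xs, diffs, yerr=ses, capsize=2, color="#88a")
    for x, c in zip(xs, cells):
        if c.code:
            ax.annotate(c.code, (x, c.difference + c.se + 0.05), ha="center")
    ax.set_xticks(xs, [str(c.percentile) for c in cells])
    ax.set_xlabel("percentile of pooled Δ distribution")
    ax.set_ylabel("difference (Δ repeats)")
    if title:
        ax.set_title(title)
    return ax
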