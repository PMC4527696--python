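"""Synthetic cohorts of Hdh(Q150) x ogg1 knock-in mice.

Generates virtual animals carrying the statistical structure the downstream
instability and phenotype analyses assume:

* inherited disease-allele sizes ~ rounded Gaussian (mean 117, SD 12 repeats),
  near-identical allele pairs in homozygotes;
* right-skewed, age/tissue/genotype-dependent somatic repeat-change (Δ)
  distributions — a floored gamma law, sign-flipped with a small contraction
  probability, whose continuous mean is calibrated so the discrete signed law
  has exactly the configured mean;
* fragment-analysis peak tables with a geometric PCR-stutter ladder and
  multiplicative trace noise, plus a birth (tail) reference table per animal;
* rotarod (best-of-3 attempts, 5 days, two speeds, 120 s ceiling) and grip
  (pass/fail per day) phenotype records with configurable sex/genotype effects
  and a post-onset motor decline for Q150/Q150 genotypes.

Default Δ means are calibrated stratum-by-stratum to the published age-window
summary (combined and homozygote-only means by OGG1 status), the striatum
10-week means (4.89 vs 2.04 repeats) and the hippocampal knockout difference
(2.20 repeats).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError
from .fragments import (
    DEFAULT_FLANK_BP,
    DEFAULT_UNIT_BP,
    PeakRecord,
    PeakTable,
    RepeatDistribution,
    repeats_to_size,
)

HD_ZYGOSITIES = ("wt/wt", "Q150/wt", "Q150/Q150")
OGG1_STATUSES = ("+/+", "+/-", "-/-")

#: number of disease-length alleles per zygosity
_N_DISEASE = {"wt/wt": 0, "Q150/wt": 1, "Q150/Q150": 2}

DEFAULT_AGE_GROUPS = (
    (5, 10),
    (11, 20),
    (21, 30),
    (31, 40),
    (41, 60),
    (61, 80),
    (81, 120),
)
DEFAULT_TISSUES = ("STR", "HIP", "CBL", "CTX")

#: expectation of the maximum of three standard normals (starting point for
#: centring attempt noise so the best-of-3 daily score is unbiased)
_MAX3_NORMAL = 3.0 / (2.0 * math.sqrt(math.pi))


@functools.lru_cache(maxsize=4096)
def _attempt_centre(mu: float, sigma: float, ceiling: float) -> float:
    """Centre of the attempt-noise law so E[best of 3 attempts] == mu.

    Attempts are clip(N(c, sigma), 0, ceiling); the daily best is the max of
    three, so E[best] = ∫ (1 - Φ³((t-c)/σ)) dt over [0, ceiling].  Solving
    for c makes the protocol score unbiased for the structural mean even
    where the ceiling truncates (the generator's contract is on the
    expected score, not the raw attempt)."""
    if sigma == 0:
        return min(mu, ceiling)
    mu = min(mu, ceiling - 1e-9)
    grid = np.linspace(0.0, ceiling, 481)

    def expected_best(c: float) -> float:
        cdf = stats.norm.cdf((grid - c) / sigma) ** 3
        return float(np.trapezoid(1.0 - cdf, grid))

    lo = mu - (_MAX3_NORMAL + 3.0) * sigma
    hi = mu + sigma
    return float(optimize.brentq(
        lambda c: expected_best(c) - mu, lo, hi, xtol=1e-6
    ))


def age_group_label(group: tuple[int, int]) -> str:
    return f"{group[0]}-{group[1]}"


def age_group_midpoint(group: tuple[int, int]) -> float:
    return 0.5 * (group[0] + group[1])


@dataclass(frozen=True)
class GenotypeSpec:
    """One of the nine genotypes of the Hdh(Q150/wt) x ogg1(+/-) cross."""

    hd_zygosity: str
    ogg1_status: str

    def __post_init__(self):
        if self.hd_zygosity not in HD_ZYGOSITIES:
            raise ConfigurationError(f"unknown Hdh zygosity {self.hd_zygosity!r}")
        if self.ogg1_status not in OGG1_STATUSES:
            raise ConfigurationError(f"unknown ogg1 status {self.ogg1_status!r}")

    @property
    def n_disease_alleles(self) -> int:
        return _N_DISEASE[self.hd_zygosity]

    @property
    def is_carrier(self) -> bool:
        return self.n_disease_alleles > 0

    def label(self) -> str:
        return f"Hdh({self.hd_zygosity})/ogg1({self.ogg1_status})"


#: the six genotypes the analysis focuses on (no ogg1 heterozygotes)
FOCUS_GENOTYPES = tuple(
    GenotypeSpec(z, o) for z in HD_ZYGOSITIES for o in ("+/+", "-/-")
)


# ---------------------------------------------------------------------------
# default expansion-mean calibration

# per-zygosity pooled-brain mean Δ by age window and OGG1 status.  The four
# early windows reproduce the published age summary: homozygote values are the
# printed homozygote-only means; heterozygote values are 2*combined - homo so
# that the combined-genotype means are also exact.  Later windows express the
# published narrative that the knockout difference vanishes (and can reverse)
# past 40 weeks.
_POOLED_MEANS: dict[str, dict[str, dict[str, float]]] = {
    "Q150/Q150": {
        "+/+": {"5-10": 4.68, "11-20": 5.48, "21-30": 3.17, "31-40": 4.47,
                "41-60": 5.20, "61-80": 5.50, "81-120": 6.00},
        "-/-": {"5-10": 1.25, "11-20": 3.37, "21-30": 2.59, "31-40": 5.19,
                "41-60": 5.20, "61-80": 5.80, "81-120": 6.30},
    },
    "Q150/wt": {
        "+/+": {"5-10": 5.52, "11-20": 5.22, "21-30": 4.61, "31-40": 5.43,
                "41-60": 5.20, "61-80": 5.50, "81-120": 6.00},
        "-/-": {"5-10": 1.43, "11-20": 2.73, "21-30": 4.77, "31-40": 3.35,
                "41-60": 5.20, "61-80": 5.80, "81-120": 6.30},
    },
}

# tissue multipliers (mean 1 within each OGG1 status) allocating the pooled
# mean across brain regions; chosen so the striatum 10-week homozygote means
# and the hippocampal/cerebellar knockout differences match the published
# values while every window's pooled mean is preserved.
_TISSUE_FACTORS: dict[str, dict[str, float]] = {
    "+/+": {"STR": 4.89 / 4.68, "HIP": 1.0, "CBL": 1.0,
            "CTX": 4.0 - 4.89 / 4.68 - 2.0},
    "-/-": {"STR": 2.04 / 1.25, "HIP": 0.850081, "CBL": 0.882496,
            "CTX": 4.0 - 2.04 / 1.25 - 0.850081 - 0.882496},
}


def default_expansion_table(
    age_groups: Iterable[tuple[int, int]] = DEFAULT_AGE_GROUPS,
    tissues: Iterable[str] = DEFAULT_TISSUES,
) -> dict[tuple[str, str, str, str], float]:
    """Mean Δ-repeats per (zygosity, ogg1, tissue, age-group label)."""
    table: dict[tuple[str, str, str, str], float] = {}
    for zyg, by_ogg1 in _POOLED_MEANS.items():
        for ogg1, by_window in by_ogg1.items():
            for group in age_groups:
                label = age_group_label(group)
                if label not in by_window:
                    continue
                pooled = by_window[label]
                for tissue in tissues:
                    factor = _TISSUE_FACTORS[ogg1].get(tissue, 1.0)
                    table[(zyg, ogg1, tissue, label)] = pooled * factor
    return table


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PhenotypeParams:
    """Structural parameters of the motor-performance model (seconds)."""

    grand_mean: float = 91.9
    female_effect: float = 7.7
    ogg1ko_effect: float = 11.0
    hd_homo_effect: float = -23.7
    residual_sd: float = 20.0
    ceiling: float = 120.0
    #: week at which post-onset motor decline starts, per (zygosity, ogg1)
    decline_onset_week: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("Q150/Q150", "+/+"): 12.0, ("Q150/Q150", "-/-"): 42.0}
    )
    decline_rate: float = 6.0  # s lost per week past onset
    decline_floor: float = 25.0  # worst mean score the decline reaches
    #: seconds lost per repeat of an animal's mean somatic change (0 = off)
    expansion_coupling: float = 0.0
    #: per-day grip FAIL logit: (intercept, slope per week) by (zygosity, ogg1)
    grip_fail_logit: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("Q150/Q150", "+/+"): (-1.70, 0.10),
            ("Q150/Q150", "-/-"): (-3.20, 0.10),
            ("Q150/wt", "+/+"): (-2.70, 0.10),
            ("Q150/wt", "-/-"): (-4.20, 0.10),
        }
    )
    grip_fail_logit_default: tuple[float, float] = (-6.0, 0.02)

    def validate(self, age_groups: Iterable[tuple[int, int]]) -> None:
        if self.ceiling <= 0:
            raise ConfigurationError("ceiling must be positive")
        if self.residual_sd < 0:
            raise ConfigurationError("residual_sd must be >= 0")
        for geno, week in self.decline_onset_week.items():
            if week <= 0:
                raise ConfigurationError(
                    f"decline onset {week} for {geno} must be a positive week"
                )

    def mean_attempt_time(self, sex: str, genotype: GenotypeSpec, age_weeks: float,
                          mean_change: float = 0.0) -> float:
        """Expected rotarod attempt time before noise and ceiling."""
        mu = self.grand_mean
        if sex == "F":
            mu += self.female_effect
        if genotype.ogg1_status == "-/-":
            mu += self.ogg1ko_effect
        if genotype.hd_zygosity == "Q150/Q150":
            mu += self.hd_homo_effect
        onset = self.decline_onset_week.get(
            (genotype.hd_zygosity, genotype.ogg1_status)
        )
        if onset is not None and age_weeks > onset:
            mu -= self.decline_rate * (age_weeks - onset)
            mu = max(mu, self.decline_floor)
        mu -= self.expansion_coupling * mean_change
        return mu

    def grip_day_fail_prob(self, genotype: GenotypeSpec, age_weeks: float) -> float:
        icpt, slope = self.grip_fail_logit.get(
            (genotype.hd_zygosity, genotype.ogg1_status), self.grip_fail_logit_default
        )
        eta = icpt + slope * age_weeks
        return 1.0 / (1.0 + math.exp(-eta))


@dataclass
class CohortConfig:
    """Everything that determines a synthetic cohort (seed included)."""

    seed: int = 0
    animals_per_cell: int = 20
    genotypes: tuple[GenotypeSpec, ...] = FOCUS_GENOTYPES
    age_groups: tuple[tuple[int, int], ...] = DEFAULT_AGE_GROUPS
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    inherited_mean: float = 117.0
    inherited_sd: float = 12.0
    #: SD (repeats) of the second allele around the first in homozygotes
    allele_sibling_sd: float = 1.5
    expansion_mean_table: dict[tuple[str, str, str, str], float] | None = None
    expansion_shape: float = 1.5
    contraction_prob: float = 0.05
    #: between-animal lognormal CV of the stratum Δ mean
    animal_mean_cv: float = 0.3
    #: within-sample allele-peak SD in repeats (the "single narrow Gaussian")
    peak_width: float = 1.5
    stutter_decay: float = 0.35
    stutter_plus1: float = 0.10
    trace_noise_cv: float = 0.05
    trace_scale: float = 10_000.0
    flank_bp: float = DEFAULT_FLANK_BP
    unit_bp: float = DEFAULT_UNIT_BP
    #: multiplier on every configured Δ mean (scavenger-treatment arm < 1)
    expansion_scale: float = 1.0
    treatment_arm: str = "none"
    male_fraction: float | None = None  # None = balanced within 1 per stratum
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)

    def __post_init__(self):
        if self.expansion_mean_table is None:
            self.expansion_mean_table = default_expansion_table(
                self.age_groups, self.tissues
            )
        self.validate()

    def validate(self) -> None:
        if self.animals_per_cell < 1:
            raise ConfigurationError("animals_per_cell must be >= 1")
        if self.inherited_sd < 0:
            raise ConfigurationError("inherited_sd must be >= 0")
        for name in ("contraction_prob",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.contraction_prob >= 0.5:
            raise ConfigurationError(
                "contraction_prob must be < 0.5 for a positive calibrated mean"
            )
        for name in ("stutter_decay", "stutter_plus1", "trace_noise_cv",
                     "animal_mean_cv", "peak_width", "expansion_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.expansion_shape <= 0:
            raise ConfigurationError("expansion_shape must be positive")
        if self.treatment_arm not in ("none", "scavenger"):
            raise ConfigurationError(f"unknown treatment arm {self.treatment_arm!r}")
        for mean in (self.expansion_mean_table or {}).values():
            if mean < 0:
                raise ConfigurationError("configured Δ means must be >= 0")
        self.phenotype.validate(self.age_groups)

    def stratum_mean(self, genotype: GenotypeSpec, tissue: str,
                     age_group: tuple[int, int]) -> float:
        key = (genotype.hd_zygosity, genotype.ogg1_status, tissue,
               age_group_label(age_group))
        if key not in self.expansion_mean_table:
            raise ConfigurationError(
                f"expansion_mean_table has no entry for stratum {key}"
            )
        return self.expansion_mean_table[key] * self.expansion_scale


@dataclass
class Animal:
    """One virtual mouse."""

    id: str
    sex: str
    genotype: GenotypeSpec
    age_weeks: int
    age_group: tuple[int, int]
    inherited_alleles: tuple[int, ...]
    treatment_arm: str = "none"
    #: animal-level multiplier on the stratum Δ mean (biological scatter)
    expansion_factor: float = 1.0

    def __post_init__(self):
        if len(self.inherited_alleles) != self.genotype.n_disease_alleles:
            raise ConfigurationError(
                f"{self.genotype.hd_zygosity} requires "
                f"{self.genotype.n_disease_alleles} disease allele(s)"
            )
        if any(a < 1 for a in self.inherited_alleles):
            raise ConfigurationError("inherited repeat counts must be >= 1")


@dataclass
class Cohort:
    """A generated cohort: animals, peak tables and performance records."""

    config: CohortConfig
    animals: list[Animal]
    #: sample_id -> PeakTable; birth references carry tissue TAIL
    peak_tables: dict[str, PeakTable]
    performance: pd.DataFrame

    def metadata(self) -> pd.DataFrame:
        rows = []
        for a in self.animals:
            alleles = list(a.inherited_alleles) + [None, None]
            rows.append(
                {
                    "animal_id": a.id,
                    "sex": a.sex,
                    "hd_zygosity": a.genotype.hd_zygosity,
                    "ogg1_status": a.genotype.ogg1_status,
                    "age_weeks": a.age_weeks,
                    "age_group": age_group_label(a.age_group),
                    "treatment_arm": a.treatment_arm,
                    "inherited_allele_1": alleles[0],
                    "inherited_allele_2": alleles[1],
                }
            )
        return pd.DataFrame(rows)

    def birth_table(self, animal_id: str) -> PeakTable:
        return self.peak_tables[f"{animal_id}:TAIL"]

    def tissue_table(self, animal_id: str, tissue: str) -> PeakTable:
        return self.peak_tables[f"{animal_id}:{tissue}"]

    def write(self, outdir) -> None:
        from pathlib import Path

        from .fragments import write_calibration, write_peak_table

        outdir = Path(outdir)
        peaks_dir = outdir / "peaks"
        peaks_dir.mkdir(parents=True, exist_ok=True)
        self.metadata().to_csv(outdir / "metadata.csv", index=False)
        self.performance.to_csv(
            outdir / "performance.csv", index=False, float_format="%.6f"
        )
        write_calibration(
            peaks_dir / "calibration.json", self.config.flank_bp, self.config.unit_bp
        )
        for sample_id, table in self.peak_tables.items():
            write_peak_table(table, peaks_dir / f"{sample_id.replace(':', '_')}.csv")


# ---------------------------------------------------------------------------
# somatic Δ law


def _floored_gamma_pmf(mean_cont: float, shape: float) -> np.ndarray:
    """pmf of floor(G), G ~ gamma(shape, mean mean_cont); index = value."""
    dist = stats.gamma(shape, scale=mean_cont / shape)
    upper = max(2, int(math.ceil(dist.ppf(1.0 - 1e-12))) + 1)
    edges = np.arange(0, upper + 1, dtype=float)
    cdf = dist.cdf(edges)
    pmf = np.diff(cdf)
    pmf[-1] += 1.0 - cdf[-1]
    return pmf


def somatic_delta_pmf(
    mean: float, shape: float = 1.5, contraction_prob: float = 0.05
) -> dict[int, float]:
    """Signed integer Δ law with exactly the requested mean.

    Positive part: floored gamma; with probability ``contraction_prob`` the
    draw is negated (contraction).  The continuous gamma mean is solved so the
    final discrete signed law has mean ``mean`` despite the floor.
    """
    if mean < 0:
        raise ConfigurationError(f"configured Δ mean must be >= 0, got {mean}")
    if not 0 <= contraction_prob < 0.5:
        raise ConfigurationError("contraction_prob must be in [0, 0.5)")
    if mean == 0:
        return {0: 1.0}
    target = mean / (1.0 - 2.0 * contraction_prob)

    def centred(m: float) -> float:
        pmf = _floored_gamma_pmf(m, shape)
        return float(np.arange(pmf.size) @ pmf) - target

    lo, hi = max(target * 0.25, 1e-6), target + 2.0
    while centred(hi) < 0:
        hi *= 1.6
    while centred(lo) > 0:
        lo *= 0.5
    m = optimize.brentq(centred, lo, hi, xtol=1e-10)
    pos = _floored_gamma_pmf(m, shape)
    law: dict[int, float] = {}
    for n, p in enumerate(pos):
        if p <= 0:
            continue
        law[n] = law.get(n, 0.0) + (1.0 - contraction_prob) * p
        law[-n] = law.get(-n, 0.0) + contraction_prob * p
    total = sum(law.values())
    return {k: v / total for k, v in sorted(law.items())}


def _gaussian_kernel(sd: float) -> tuple[np.ndarray, int]:
    """Discretized centred Gaussian pmf on integers; returns (pmf, radius)."""
    if sd <= 0:
        return np.array([1.0]), 0
    radius = max(1, int(math.ceil(6.0 * sd)))
    n = np.arange(-radius, radius + 1, dtype=float)
    pmf = stats.norm.cdf(n + 0.5, scale=sd) - stats.norm.cdf(n - 0.5, scale=sd)
    return pmf / pmf.sum(), radius


def draw_inherited_allele(config: CohortConfig, rng: np.random.Generator) -> int:
    """One inherited disease-allele size: rounded Gaussian, at least 1."""
    if config.inherited_sd == 0:
        return max(1, int(round(config.inherited_mean)))
    draw = rng.normal(config.inherited_mean, config.inherited_sd)
    return max(1, int(np.rint(draw)))


def draw_somatic_distribution(
    animal: Animal, tissue: str, config: CohortConfig
) -> RepeatDistribution:
    """Absolute repeat-count distribution for one animal/tissue sample.

    Each inherited allele contributes an equal-weight component: the allele
    size plus the signed Δ law (scaled by the animal's expansion factor),
    broadened by the within-sample peak width.  The birth reference is the
    special case Δ ≡ 0 (use :func:`birth_distribution`).
    """
    if not animal.inherited_alleles:
        raise ConfigurationError(
            f"animal {animal.id} ({animal.genotype.hd_zygosity}) carries no "
            "disease allele; no repeat distribution is defined"
        )
    mean = config.stratum_mean(animal.genotype, tissue, animal.age_group)
    return _assemble_distribution(
        animal.inherited_alleles,
        mean * animal.expansion_factor,
        config,
    )


def birth_distribution(animal: Animal, config: CohortConfig) -> RepeatDistribution:
    """The inherited (birth/tail) distribution: Δ ≡ 0, peak width only."""
    return _assemble_distribution(animal.inherited_alleles, 0.0, config)


def _assemble_distribution(
    alleles: tuple[int, ...], mean_delta: float, config: CohortConfig
) -> RepeatDistribution:
    law = somatic_delta_pmf(
        mean_delta, config.expansion_shape, config.contraction_prob
    )
    deltas = np.fromiter(law.keys(), dtype=int)
    probs = np.fromiter(law.values(), dtype=float)
    kernel, radius = _gaussian_kernel(config.peak_width)
    lo = deltas.min() - radius
    width = deltas.max() - deltas.min() + 2 * radius + 1
    base = np.zeros(width)
    base[deltas - deltas.min() + radius] = probs
    if radius:
        base = np.convolve(base, kernel, mode="same")
    freqs: dict[int, float] = {}
    for allele in alleles:
        for i, p in enumerate(base):
            if p <= 0:
                continue
            n = allele + lo + i
            if n >= 1:
                freqs[n] = freqs.get(n, 0.0) + p / len(alleles)
    return RepeatDistribution(freqs)


# ---------------------------------------------------------------------------
# trace rendering


def render_trace(
    distribution: RepeatDistribution,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
    animal_id: str = "",
    tissue: str = "",
) -> PeakTable:
    """Render a repeat distribution as a stuttered fragment-analysis table.

    Each repeat class n yields a main peak at ``flank + unit*n`` bp plus
    stutter satellites at n-1 and n-2 (heights decaying geometrically by
    ``stutter_decay``) and n+1 (``stutter_plus1``); heights then receive
    multiplicative lognormal noise with CV ``trace_noise_cv``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ladder = {0: 1.0, -1: config.stutter_decay, -2: config.stutter_decay**2,
              1: config.stutter_plus1}
    heights: dict[int, float] = {}
    for n, f in distribution.frequencies.items():
        for offset, weight in ladder.items():
            if weight <= 0:
                continue
            m = n + offset
            if m >= 1:
                heights[m] = heights.get(m, 0.0) + f * weight
    cv = config.trace_noise_cv
    if cv > 0:
        sigma = math.sqrt(math.log1p(cv * cv))
        noise = rng.lognormal(-0.5 * sigma * sigma, sigma, size=len(heights))
    else:
        noise = np.ones(len(heights))
    peaks = []
    for (m, h), z in zip(sorted(heights.items()), noise):
        height = config.trace_scale * h * z
        if height <= 0:
            continue
        peaks.append(
            PeakRecord(
                size_bp=repeats_to_size(m, config.flank_bp, config.unit_bp),
                height=height,
                area=height,
            )
        )
    return PeakTable(sample_id=sample_id, animal_id=animal_id, tissue=tissue,
                     peaks=peaks)


# ---------------------------------------------------------------------------
# phenotype records


def generate_performance(
    animal: Animal,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    mean_change: float = 0.0,
) -> pd.DataFrame:
    """Rotarod attempts (5 days x 3 attempts x 10/20 rpm) and daily grip.

    Attempt times are ``clip(mu - c*sd + noise, 0, ceiling)`` where ``c`` is
    the expected maximum of three standard normals, so that the best-of-3
    daily score averaged over days is unbiased for the structural mean ``mu``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.phenotype
    mu = p.mean_attempt_time(animal.sex, animal.genotype, animal.age_weeks,
                             mean_change)
    centre = _attempt_centre(round(mu, 3), p.residual_sd, p.ceiling)
    fail_prob = p.grip_day_fail_prob(animal.genotype, animal.age_weeks)
    rows = []
    for day in range(1, 6):
        grip_pass = bool(rng.random() >= fail_prob)
        for speed in (10, 20):
            for attempt in range(1, 4):
                t = centre + (rng.normal(0.0, p.residual_sd) if p.residual_sd else 0.0)
                rows.append(
                    {
                        "animal_id": animal.id,
                        "day": day,
                        "attempt": attempt,
                        "speed_rpm": speed,
                        "time_s": float(np.clip(t, 0.0, p.ceiling)),
                        "grip_pass": grip_pass,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort assembly


def _sexes(n: int, config: CohortConfig, rng: np.random.Generator) -> list[str]:
    if config.male_fraction is None:
        half = [("M" if i % 2 == 0 else "F") for i in range(n)]
        return half
    return ["M" if rng.random() < config.male_fraction else "F" for _ in range(n)]


def _draw_alleles(
    genotype: GenotypeSpec, config: CohortConfig, rng: np.random.Generator
) -> tuple[int, ...]:
    n = genotype.n_disease_alleles
    if n == 0:
        return ()
    first = draw_inherited_allele(config, rng)
    if n == 1:
        return (first,)
    jitter = int(np.rint(rng.normal(0.0, config.allele_sibling_sd))) \
        if config.allele_sibling_sd > 0 else 0
    return (first, max(1, first + jitter))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort; identical config (incl. seed) ⇒ identical output.

    Every (genotype, age-group) stratum receives ``animals_per_cell`` animals
    with sexes balanced to within one.  Each carrier animal gets one birth
    (tail) peak table and one table per tissue at its sacrifice age; every
    stratum's Δ mean must be present in ``expansion_mean_table`` or a
    :class:`ConfigurationError` naming the stratum is raised up front.
    """
    config.validate()
    for genotype in config.genotypes:
        if not genotype.is_carrier:
            continue
        for group in config.age_groups:
            for tissue in config.tissues:
                config.stratum_mean(genotype, tissue, group)  # raises if absent

    rng = np.random.default_rng(config.seed)
    animals: list[Animal] = []
    peak_tables: dict[str, PeakTable] = {}
    perf_frames: list[pd.DataFrame] = []
    counter = 0
    for genotype in config.genotypes:
        for group in config.age_groups:
            sexes = _sexes(config.animals_per_cell, config, rng)
            for sex in sexes:
                counter += 1
                animal = Animal(
                    id=f"A{counter:05d}",
                    sex=sex,
                    genotype=genotype,
                    age_weeks=int(rng.integers(group[0], group[1] + 1)),
                    age_group=group,
                    inherited_alleles=_draw_alleles(genotype, config, rng),
                    treatment_arm=config.treatment_arm,
                    expansion_factor=_animal_factor(config, rng),
                )
                animals.append(animal)
                mean_changes = []
                if animal.genotype.is_carrier:
                    birth = birth_distribution(animal, config)
                    peak_tables[f"{animal.id}:TAIL"] = render_trace(
                        birth, config, rng, sample_id=f"{animal.id}:TAIL",
                        animal_id=animal.id, tissue="TAIL",
                    )
                    for tissue in config.tissues:
                        dist = draw_somatic_distribution(animal, tissue, config)
                        peak_tables[f"{animal.id}:{tissue}"] = render_trace(
                            dist, config, rng, sample_id=f"{animal.id}:{tissue}",
                            animal_id=animal.id, tissue=tissue,
                        )
                        mean_changes.append(
                            dist.mean() - float(np.mean(animal.inherited_alleles))
                        )
                coupling_summary = float(np.mean(mean_changes)) if mean_changes else 0.0
                perf_frames.append(
                    generate_performance(animal, config, rng, coupling_summary)
                )
    performance = pd.concat(perf_frames, ignore_index=True)
    return Cohort(config=config, animals=animals, peak_tables=peak_tables,
                  performance=performance)


def _animal_factor(config: CohortConfig, rng: np.random.Generator) -> float:
    cv = config.animal_mean_cv
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def scavenger_arm(config: CohortConfig, expansion_scale: float = 0.5) -> CohortConfig:
    """Config for a pharmacologically treated arm: same cohort design, Δ means
    scaled down by ``expansion_scale`` (mitochondrial ROS-scavenger treatment)."""
    return replace(config, expansion_scale=config.expansion_scale * expansion_scale,
                   treatment_arm="scavenger")
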