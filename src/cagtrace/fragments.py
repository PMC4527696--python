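"""Peak-table IO and fragment-size → repeat-count conversion.

Fragment analysis (GeneScan-style capillary electrophoresis) of the amplified
CAG tract yields, per sample, a list of peaks: fragment size in base pairs and
a height/area in arbitrary fluorescence units.  This module reads and writes
those peak tables as plain CSV, converts sizes to repeat counts with a linear
calibration (``repeats = (size_bp - flank_bp) / unit_bp``), and collapses a
peak table into a normalized frequency distribution over integer repeat
counts, optionally deconvolving the geometric PCR-stutter ladder.

The absolute calibration depends on the (assay-specific) flanking length of
the amplicon, so ``flank_bp`` is always an explicit argument; the default used
throughout the synthetic cohort is 100 bp with a 3 bp repeat unit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import (
    CalibrationError,
    EmptyDistributionError,
    EmptyTableError,
    FormatError,
)

#: canonical tissue labels accepted in peak tables
TISSUES = ("STR", "HIP", "CBL", "CTX", "TAIL", "LIVER", "BRAIN")

PEAK_COLUMNS = ("sample_id", "animal_id", "tissue", "size_bp", "height", "area")

DEFAULT_FLANK_BP = 100.0
DEFAULT_UNIT_BP = 3.0


@dataclass(frozen=True)
class PeakRecord:
    """One called peak: fragment size (bp) and intensity."""

    size_bp: float
    height: float
    area: float = 0.0

    def __post_init__(self):
        if self.size_bp <= 0:
            raise FormatError(f"peak size must be positive, got {self.size_bp}")
        if self.height < 0:
            raise FormatError(f"peak height must be >= 0, got {self.height}")


@dataclass
class PeakTable:
    """Ordered peak list for one sample (one animal, one tissue)."""

    sample_id: str
    animal_id: str
    tissue: str
    peaks: list[PeakRecord] = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.size_bp)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def max_height(self) -> float:
        return max((p.height for p in self.peaks), default=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "animal_id": self.animal_id,
                "tissue": self.tissue,
                "size_bp": [p.size_bp for p in self.peaks],
                "height": [p.height for p in self.peaks],
                "area": [p.area for p in self.peaks],
            }
        )


@dataclass
class RepeatDistribution:
    """Normalized frequency distribution over integer repeat counts."""

    frequencies: dict[int, float]

    def __post_init__(self):
        if not self.frequencies:
            raise EmptyDistributionError("repeat distribution has no support")
        clean: dict[int, float] = {}
        for k, v in self.frequencies.items():
            if v < 0:
                raise ValueError(f"negative frequency {v} at repeat {k}")
            if v > 0:
                clean[int(k)] = float(v)
        if not clean:
            raise EmptyDistributionError("repeat distribution has zero mass")
        total = sum(clean.values())
        self.frequencies = {k: v / total for k, v in sorted(clean.items())}

    @property
    def support_min(self) -> int:
        return min(self.frequencies)

    @property
    def support_max(self) -> int:
        return max(self.frequencies)

    @property
    def support(self) -> np.ndarray:
        return np.fromiter(self.frequencies.keys(), dtype=int)

    @property
    def probs(self) -> np.ndarray:
        return np.fromiter(self.frequencies.values(), dtype=float)

    def mean(self) -> float:
        return float(self.support @ self.probs)

    def var(self) -> float:
        m = self.mean()
        return float(((self.support - m) ** 2) @ self.probs)

    def total_variation(self, other: "RepeatDistribution") -> float:
        keys = set(self.frequencies) | set(other.frequencies)
        return 0.5 * sum(
            abs(self.frequencies.get(k, 0.0) - other.frequencies.get(k, 0.0))
            for k in keys
        )

    def shift(self, delta: int) -> "RepeatDistribution":
        return RepeatDistribution({k + delta: v for k, v in self.frequencies.items()})


# ---------------------------------------------------------------------------
# delimited IO


def write_peak_table(table: PeakTable, path: str | Path) -> Path:
    """Write one sample's peaks as CSV (UTF-8, dot decimal, 6 decimals)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, index=False, float_format="%.6f")
    return path


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a single-sample peak table written by :func:`write_peak_table`.

    Raises :class:`FormatError` for missing columns or malformed numbers and
    :class:`EmptyTableError` for a header-only file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "animal_id": str, "tissue": str})
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{path} contains no data") from None
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing column(s): {', '.join(missing)}")
    if df.empty:
        raise EmptyTableError(f"{path} has a header but no peaks")
    for col in ("size_bp", "height", "area"):
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            bad = df.loc[values.isna(), col].iloc[0]
            raise FormatError(f"{path}: malformed numeric value {bad!r} in column {col}")
        df[col] = values
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) != 1:
        raise FormatError(f"{path} mixes sample ids: {sample_ids.tolist()}")
    peaks = [
        PeakRecord(size_bp=r.size_bp, height=r.height, area=r.area)
        for r in df.itertuples()
    ]
    return PeakTable(
        sample_id=str(df["sample_id"].iloc[0]),
        animal_id=str(df["animal_id"].iloc[0]),
        tissue=str(df["tissue"].iloc[0]),
        peaks=peaks,
    )


def write_calibration(path: str | Path, flank_bp: float, unit_bp: float = DEFAULT_UNIT_BP) -> Path:
    """Write the sidecar recording the bp↔repeat calibration of a peak set."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"flank_bp": flank_bp, "unit_bp": unit_bp}, indent=2) + "\n")
    return path


def read_calibration(path: str | Path) -> tuple[float, float]:
    data = json.loads(Path(path).read_text())
    return float(data["flank_bp"]), float(data["unit_bp"])


def write_distribution(dist: RepeatDistribution, path: str | Path, value_col: str = "repeat") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {value_col: list(dist.frequencies), "frequency": list(dist.frequencies.values())}
    ).to_csv(path, index=False, float_format="%.9f")
    return path


def read_distribution(path: str | Path, value_col: str = "repeat") -> RepeatDistribution:
    df = pd.read_csv(path)
    if value_col not in df.columns or "frequency" not in df.columns:
        raise FormatError(f"{path} must have columns {value_col!r} and 'frequency'")
    return RepeatDistribution(dict(zip(df[value_col].astype(int), df["frequency"])))


# ---------------------------------------------------------------------------
# size <-> repeats


def size_to_repeats(size_bp: float, flank_bp: float, unit_bp: float = DEFAULT_UNIT_BP) -> float:
    """Linear bp → repeat-count conversion; exact and invertible, no rounding."""
    if unit_bp <= 0:
        raise ValueError("unit_bp must be positive")
    repeats = (size_bp - flank_bp) / unit_bp
    if repeats <= 0:
        raise CalibrationError(
            f"size {size_bp} bp is not beyond the {flank_bp} bp flank"
        )
    return repeats


def repeats_to_size(repeats: float, flank_bp: float, unit_bp: float = DEFAULT_UNIT_BP) -> float:
    return flank_bp + unit_bp * repeats


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _stutter_deconvolve(
    repeats: np.ndarray,
    heights: np.ndarray,
    stutter_decay: float,
    stutter_plus1: float,
) -> np.ndarray:
    """Divide out the geometric stutter ladder by nonnegative least squares.

    The observed height at repeat n is modelled as sum_m f(m) * s(n-m) with
    s(0)=1, s(-1)=decay, s(-2)=decay^2, s(+1)=plus1.  Solving S f = h with
    f >= 0 recovers the stutter-free distribution exactly for noiseless input.
    """
    lo, hi = int(repeats.min()), int(repeats.max())
    grid = np.arange(lo, hi + 1)
    h = np.zeros(grid.size)
    h[repeats - lo] = heights
    ladder = {0: 1.0, -1: stutter_decay, -2: stutter_decay**2, 1: stutter_plus1}
    S = np.zeros((grid.size, grid.size))
    for offset, weight in ladder.items():
        if weight <= 0:
            continue
        idx = np.arange(grid.size)
        obs = idx + offset
        ok = (obs >= 0) & (obs < grid.size)
        S[obs[ok], idx[ok]] = weight
    f, _ = nnls(S, h)
    return np.column_stack([grid, f])[f > 0]


def peaks_to_distribution(
    table: PeakTable,
    flank_bp: float,
    unit_bp: float = DEFAULT_UNIT_BP,
    min_rel_height: float = 0.05,
    stutter_correct: bool = False,
    stutter_decay: float = 0.35,
    stutter_plus1: float = 0.10,
) -> RepeatDistribution:
    """Collapse a peak table to a normalized integer-repeat distribution.

    Peaks below ``min_rel_height`` times the tallest peak are discarded, sizes
    are converted with the linear calibration and rounded to the nearest
    integer repeat (half away from zero; ties cannot occur for exact 3 bp
    spacing), and heights are renormalized to sum to one.  With
    ``stutter_correct`` the configured geometric stutter ladder is divided out
    first (nonnegative least squares, see :func:`_stutter_deconvolve`).
    """
    if len(table) == 0:
        raise EmptyTableError(f"sample {table.sample_id}: no peaks")
    cutoff = min_rel_height * table.max_height
    kept = [p for p in table.peaks if p.height >= cutoff and p.height > 0]
    if not kept:
        raise EmptyDistributionError(
            f"sample {table.sample_id}: all peaks below threshold {cutoff:.3g}"
        )
    freqs: dict[int, float] = {}
    for p in kept:
        n = _round_half_away(size_to_repeats(p.size_bp, flank_bp, unit_bp))
        if n <= 0:
            raise CalibrationError(
                f"sample {table.sample_id}: peak at {p.size_bp} bp rounds to repeat {n}"
            )
        freqs[n] = freqs.get(n, 0.0) + p.height
    if stutter_correct and len(freqs) > 1:
        arr = _stutter_deconvolve(
            np.fromiter(freqs.keys(), dtype=int),
            np.fromiter(freqs.values(), dtype=float),
            stutter_decay,
            stutter_plus1,
        )
        if arr.size == 0:
            raise EmptyDistributionError(
                f"sample {table.sample_id}: stutter correction removed all mass"
            )
        freqs = {int(n): float(f) for n, f in arr}
    return RepeatDistribution(freqs)
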