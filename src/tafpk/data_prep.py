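"""Observation ingestion and normalization.

Covers the data-handling rules applied before any modeling: imputation of
below-LLOQ (BLQ) concentrations at half the assay LLOQ, normalization of
per-sample LLOQs by the median sample mass or cell count, conversion of
assay units to molar concentrations, plateau-window summaries, and
harmonization of literature summary statistics (median + range or
median/mean + SD) to median + IQR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model_core import MOLAR

__all__ = [
    "MATRICES",
    "DEFAULT_LLOQ",
    "ConcentrationRecord",
    "SummaryStats",
    "impute_bloq",
    "to_molar",
    "range_coefficient",
    "estimate_median_iqr",
    "plateau_summary",
    "PlateauSummary",
    "read_observations_csv",
]

# canonical reporting units per matrix
MATRICES = {
    "plasma_taf": "ng/mL",
    "plasma_tfv": "ng/mL",
    "pbmc_tfvdp": "fmol/1e6 cells",
    "vaginal_fluid_tfv": "ng/mg",
    "rectal_fluid_tfv": "ng/mg",
    "vaginal_tissue": "ng/mg",
    "rectal_tissue": "ng/mg",
}

# assay LLOQs; per_sample entries are in ng (or fmol) per sample and must be
# normalized by the median sample mass (mg) or cell count (1e6) before use
DEFAULT_LLOQ = {
    "plasma_taf": {"value": 0.03, "per_sample": False},
    "plasma_tfv": {"value": 1.0, "per_sample": False},
    "pbmc_tfvdp": {"value": 5.0, "per_sample": True},   # fmol/sample
    "vaginal_fluid_tfv": {"value": 0.25, "per_sample": True},  # ng/sample
    "rectal_fluid_tfv": {"value": 0.25, "per_sample": True},
    "vaginal_tissue": {"value": 0.05, "per_sample": True},
    "rectal_tissue": {"value": 0.05, "per_sample": True},
}

# normal-theory z for the quartiles
_Z_QUARTILE = float(norm.ppf(0.75))  # 0.6745


@dataclass
class ConcentrationRecord:
    """One observation in canonical units, with its BLQ status."""

    study: str
    animal: str
    group: str
    matrix: str
    time_d: float
    value: float  # canonical units; lloq/2 for imputed BLQ records
    lloq: float  # canonical units
    is_bloq: bool = False
    raw_value: Optional[float] = None
    raw_units: Optional[str] = None
    normalizer: Optional[float] = None  # sample mass (mg) or cells (1e6)

    def __post_init__(self):
        if self.matrix not in MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if self.time_d < 0:
            raise ValueError("time must be non-negative")


def impute_bloq(lloq: float, normalizer: Optional[float] = None,
                per_sample: bool = False) -> float:
    """Imputed value for a BLQ record: half the (normalized) assay LLOQ.

    When the LLOQ is expressed per sample (``per_sample=True``), it is first
    divided by the median sample mass/cell count ``normalizer``, then halved.
    """
    if not lloq > 0:
        raise ValueError("LLOQ must be strictly positive")
    if per_sample:
        if normalizer is None or not normalizer > 0:
            raise ValueError(
                "a per-sample LLOQ requires a positive median mass/cell-count"
                " normalizer")
        lloq = lloq / normalizer
    return lloq / 2.0


def to_molar(value, matrix: str):
    """Convert a canonical-unit concentration to µM.

    Supported: plasma TFV (ng/mL / 287.21 g/mol -> 1.0 ng/mL = 3.5e-3 µM) and
    PBMC TFV-DP (fmol/1e6 cells over a 0.2 µL mean cell volume ->
    1.0 fmol/1e6 cells = 5.0e-3 µM).
    """
    if matrix == "plasma_tfv":
        return MOLAR.plasma_ng_ml_to_uM(value)
    if matrix == "pbmc_tfvdp":
        return MOLAR.pbmc_fmol_to_uM(value)
    raise ValueError(f"no molar conversion defined for matrix {matrix!r}")


@dataclass
class SummaryStats:
    """Median and interquartile range, with estimation provenance."""

    n: int
    median: float
    q1: float
    q3: float
    provenance: str  # reported | estimated_from_range | estimated_from_sd

    def __post_init__(self):
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("require q1 <= median <= q3")


def range_coefficient(n: int) -> float:
    """Expected range of a normal sample of size n, in SD units.

    The range-to-SD coefficient xi(n) = 2*Phi^-1((n - 0.375)/(n + 0.25)),
    so SD ~= (max - min)/xi(n).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    return 2.0 * float(norm.ppf((n - 0.375) / (n + 0.25)))


def estimate_median_iqr(
    n: int,
    median: Optional[float] = None,
    low: Optional[float] = None,
    high: Optional[float] = None,
    sd: Optional[float] = None,
    mean: Optional[float] = None,
    q1: Optional[float] = None,
    q3: Optional[float] = None,
) -> SummaryStats:
    """Harmonize a reported summary to median + IQR.

    Accepted input combinations, in order of preference:

    * ``median, q1, q3`` — passed through unchanged (provenance "reported");
    * ``median, sd`` or ``mean, sd`` — normal-theory quartiles
      ``center -/+ 0.6745*sd`` (the mean stands in for the median);
    * ``median, low, high`` — the SD is first estimated from the range via
      the n-dependent coefficient of :func:`range_coefficient`, then
      normal-theory quartiles are applied.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if median is not None and q1 is not None and q3 is not None:
        return SummaryStats(n, median, q1, q3, "reported")
    center = median if median is not None else mean
    if center is None:
        raise ValueError("need a median (or mean) to locate the distribution")
    if sd is not None:
        if sd < 0:
            raise ValueError("SD must be non-negative")
        half = _Z_QUARTILE * sd
        return SummaryStats(n, center, center - half, center + half,
                            "estimated_from_sd")
    if low is not None and high is not None:
        if not (low <= center <= high):
            raise ValueError("require min <= median <= max")
        sd_hat = (high - low) / range_coefficient(n)
        half = _Z_QUARTILE * sd_hat
        return SummaryStats(n, center, center - half, center + half,
                            "estimated_from_range")
    raise ValueError("supply either (q1, q3), an SD, or a (min, max) range")


@dataclass
class PlateauSummary:
    n: int
    pct_above_lloq: float
    median: float
    q1: float
    q3: float


def plateau_summary(records: pd.DataFrame, window: tuple[float, float],
                    ) -> PlateauSummary:
    """Summary over an analyte-concentration plateau window (study days).

    Filters records to ``window`` (inclusive), reports the count, the percent
    of quantifiable (non-BLQ) records — judged from the pre-imputation flags,
    never from values — and the median and Q1-Q3 of the values with BLQ
    records imputed at LLOQ/2.  Empirical quartiles use linear (type-7)
    interpolation.
    """
    lo, hi = window
    if not hi >= lo:
        raise ValueError("window end must not precede its start")
    sub = records[(records["time_d"] >= lo) & (records["time_d"] <= hi)]
    if sub.empty:
        raise ValueError(f"no records in window [{lo}, {hi}]")
    bloq = sub["is_bloq"].astype(bool).to_numpy()
    values = sub["value"].to_numpy(dtype=float).copy()
    values[bloq] = sub["lloq"].to_numpy(dtype=float)[bloq] / 2.0
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return PlateauSummary(
        n=int(len(sub)),
        pct_above_lloq=100.0 * float((~bloq).mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


_CANONICAL_COLUMNS = ["study", "animal", "group", "matrix", "time_d", "value",
                      "lloq", "bloq"]


def read_observations_csv(path, schema: Optional[dict] = None,
                          time_unit: str = "d") -> pd.DataFrame:
    """Read an observations CSV into the canonical schema.

    ``schema`` optionally maps the file's column names onto the canonical
    ones (study, animal, group, matrix, time_d, value, lloq, bloq); hours
    are converted to days when ``time_unit='h'``.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in _CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observations file missing columns: {missing}")
    df = df[_CANONICAL_COLUMNS].copy()
    if time_unit == "h":
        df["time_d"] = df["time_d"] / 24.0
    elif time_unit != "d":
        raise ValueError("time_unit must be 'd' or 'h'")
    df["bloq"] = df["bloq"].astype(int)
    df["is_bloq"] = df["bloq"].astype(bool)
    bad = df["matrix"][~df["matrix"].isin(MATRICES)].unique()
    if len(bad):
        raise ValueError(f"unknown matrices in file: {sorted(bad)}")
    return df
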