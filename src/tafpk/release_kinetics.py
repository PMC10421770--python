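"""Implant release-kinetics computations.

Orifice surface area, residual-drug release-rate estimation, zero-order
(linear) release regression with confidence bands, in vitro-in vivo
correlation (IVIVC), body-weight normalization, and multi-implant
aggregation per animal/pocket.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ImplantRecord",
    "ReleaseSeries",
    "ZeroOrderFit",
    "orifice_surface_area",
    "in_vivo_release_rate",
    "zero_order_regression",
    "ivivc",
    "weight_adjusted_rate",
    "aggregate_pocket",
    "release_series_from_records",
    "read_implants_csv",
    "rates_table",
]


@dataclass
class ImplantRecord:
    """One implant: fabrication geometry plus drug accounting."""

    animal: str
    initial_load: float  # mg
    residual: Optional[float]  # mg; None when the implant was not recovered
    days_in_situ: float
    length: float = 40.0  # mm
    outer_diameter: float = 2.3  # mm
    n_orifices: int = 1
    orifice_diameter: float = 0.5  # mm
    pocket: str = "1"
    study: str = ""
    recovered: bool = True

    def __post_init__(self):
        if not self.days_in_situ > 0:
            raise ValueError("days_in_situ must be positive")
        if self.n_orifices < 1:
            raise ValueError("need at least one orifice")
        if self.recovered:
            if self.residual is None:
                raise ValueError("recovered implant must report a residual")
            if self.residual > self.initial_load:
                raise ValueError("residual cannot exceed the initial load")
            if self.residual < 0:
                raise ValueError("residual cannot be negative")


def orifice_surface_area(n: int, d: float) -> float:
    """Total orifice surface area S.A. = n * pi * (d/2)^2 (mm^2)."""
    if n < 1:
        raise ValueError("orifice count must be at least 1")
    if not d > 0:
        raise ValueError("orifice diameter must be positive")
    return n * math.pi * (d / 2.0) ** 2


def in_vivo_release_rate(record: ImplantRecord) -> float:
    """Average in vivo release rate from residual drug analysis (mg/d).

    (initial load - residual) / days in situ; requires a recovered implant.
    """
    if not record.recovered or record.residual is None:
        raise ValueError("cannot compute a release rate for a missing implant")
    return (record.initial_load - record.residual) / record.days_in_situ


@dataclass
class ReleaseSeries:
    """Cumulative drug released (mg) versus time (d) for one group."""

    time: np.ndarray
    cumulative_released: np.ndarray
    group: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.cumulative_released = np.asarray(self.cumulative_released,
                                              dtype=float)
        if self.time.shape != self.cumulative_released.shape:
            raise ValueError("time and release arrays must align")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ZeroOrderFit:
    """Simple linear regression of cumulative release on time."""

    slope: float  # mg/d
    intercept: float  # mg
    slope_se: float
    intercept_se: float
    residual_sd: float
    time: np.ndarray = field(repr=False)
    mean_lower: np.ndarray = field(repr=False)  # 95% confidence band, lower
    mean_upper: np.ndarray = field(repr=False)  # 95% confidence band, upper

    def predict(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)


def zero_order_regression(series: ReleaseSeries,
                          alpha: float = 0.05) -> ZeroOrderFit:
    """OLS fit of cumulative release versus time with confidence bands.

    Zero-order (constant-rate) release gives a straight line whose slope is
    the release rate in mg/d.  The bands are the standard OLS confidence
    interval for the regression mean, using t-quantiles.
    """
    if series.time.size < 3:
        raise ValueError("need at least 3 timepoints for a regression")
    x = sm.add_constant(series.time)
    fit = sm.OLS(series.cumulative_released, x).fit()
    pred = fit.get_prediction(x).summary_frame(alpha=alpha)
    return ZeroOrderFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        residual_sd=float(np.sqrt(fit.mse_resid)),
        time=series.time.copy(),
        mean_lower=pred["mean_ci_lower"].to_numpy(),
        mean_upper=pred["mean_ci_upper"].to_numpy(),
    )


def ivivc(in_vitro_rate: float, in_vivo_rate: float) -> float:
    """In vitro-in vivo correlation: in vivo rate / in vitro rate.

    Conventionally reported to two significant figures (round separately for
    display); ivivc(x, x) == 1 for any x > 0.
    """
    if not in_vitro_rate > 0 or not in_vivo_rate > 0:
        raise ValueError("both release rates must be strictly positive")
    return in_vivo_rate / in_vitro_rate


def weight_adjusted_rate(rate_mg_d: float, weight_kg: float) -> float:
    """Body-weight-adjusted release rate, µg/kg/d."""
    if not weight_kg > 0:
        raise ValueError("body weight must be positive")
    if rate_mg_d < 0:
        raise ValueError("rate must be non-negative")
    return rate_mg_d * 1000.0 / weight_kg


def aggregate_pocket(records: Sequence[ImplantRecord]) -> tuple[float, bool]:
    """Total release rate for one animal's implants (mg/d).

    Returns ``(total_rate, complete)``; missing (unrecovered) implants are
    excluded — never imputed — with ``complete=False`` and a warning.
    """
    records = list(records)
    if not records:
        raise ValueError("no implant records for this animal")
    animals = {r.animal for r in records}
    if len(animals) > 1:
        raise ValueError(f"records span multiple animals: {sorted(animals)}")
    recovered = [r for r in records if r.recovered]
    if not recovered:
        raise ValueError(f"no recovered implants for animal {records[0].animal}")
    complete = len(recovered) == len(records)
    if not complete:
        warnings.warn(
            f"animal {records[0].animal}: {len(records) - len(recovered)} "
            "implant(s) missing at collection; total rate is a lower bound",
            stacklevel=2)
    return sum(in_vivo_release_rate(r) for r in recovered), complete


def release_series_from_records(records: Sequence[ImplantRecord],
                                group: str = "") -> ReleaseSeries:
    """Serial-sacrifice design: mean cumulative release per sacrifice day.

    Each timepoint's cumulative release is the group mean of
    (load - residual) over the recovered implants sacrificed that day.
    """
    rows = [(r.days_in_situ, r.initial_load - r.residual)
            for r in records if r.recovered]
    if not rows:
        raise ValueError("no recovered implants in the series")
    df = pd.DataFrame(rows, columns=["day", "released"])
    mean = df.groupby("day")["released"].mean().sort_index()
    return ReleaseSeries(time=mean.index.to_numpy(),
                         cumulative_released=mean.to_numpy(), group=group)


_IMPLANT_COLUMNS = {
    "study": "study", "animal": "animal", "pocket": "pocket",
    "length_mm": "length", "n_orifices": "n_orifices",
    "orifice_d_mm": "orifice_diameter", "load_mg": "initial_load",
    "residual_mg": "residual", "days": "days_in_situ",
    "recovered": "recovered",
}


def read_implants_csv(path) -> list[ImplantRecord]:
    """Read implant records from CSV (columns: study, animal, pocket,
    length_mm, n_orifices, orifice_d_mm, load_mg, residual_mg, days,
    recovered)."""
    df = pd.read_csv(path)
    missing = [c for c in _IMPLANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"implants file missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        recovered = bool(int(row["recovered"]))
        residual = float(row["residual_mg"]) if recovered else None
        records.append(ImplantRecord(
            study=str(row["study"]), animal=str(row["animal"]),
            pocket=str(row["pocket"]), length=float(row["length_mm"]),
            n_orifices=int(row["n_orifices"]),
            orifice_diameter=float(row["orifice_d_mm"]),
            initial_load=float(row["load_mg"]), residual=residual,
            days_in_situ=float(row["days"]), recovered=recovered,
        ))
    return records


def rates_table(records: Sequence[ImplantRecord],
                weights_kg: Optional[dict] = None) -> pd.DataFrame:
    """Per-animal release-rate table: total rate, completeness flag, and the
    body-weight-adjusted rate when a weight is supplied."""
    by_animal: dict[str, list[ImplantRecord]] = {}
    for r in records:
        by_animal.setdefault(r.animal, []).append(r)
    rows = []
    for animal, recs in sorted(by_animal.items()):
        try:
            total, complete = aggregate_pocket(recs)
        except ValueError:
            rows.append({"animal": animal, "n_implants": len(recs),
                         "n_recovered": 0, "rate_mg_d": np.nan,
                         "complete": False, "rate_ug_kg_d": np.nan})
            continue
        weight = (weights_kg or {}).get(animal)
        rows.append({
            "animal": animal,
            "n_implants": len(recs),
            "n_recovered": sum(r.recovered for r in recs),
            "rate_mg_d": total,
            "complete": complete,
            "rate_ug_kg_d": (weight_adjusted_rate(total, weight)
                             if weight else np.nan),
        })
    return pd.DataFrame(rows)
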