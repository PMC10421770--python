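"""Structural prodrug->metabolite->anabolite model for subdermal TAF delivery.

Tenofovir alafenamide (TAF) released from a subcutaneous implant (or given as
an IV infusion) hydrolyzes to tenofovir (TFV) essentially instantaneously on
absorption; circulating TFV distributes over a two-compartment system and is
converted intracellularly to tenofovir diphosphate (TFV-DP), the active
anabolite measured in peripheral blood mononuclear cells (PBMCs).

The state vector tracks molar amounts (µmol TFV-equivalents):

* ``A_depot`` — drug remaining in the subcutaneous depot,
* ``A_c``     — TFV in the central (plasma) compartment,
* ``A_p``     — TFV in the peripheral compartment,
* ``A_dp``    — TFV-DP in the PBMC compartment.

with first-order absorption ``ka = 1/MAT``, apparent bioavailability ``F``
applied at the depot->central transfer (the IV route bypasses the depot and
has ``F`` identically 1), linear disposition ``Cl, V, Clp, Vp``, and a
TFV->TFV-DP formation term that is linear (``vmkm * C``) by default or
saturable Michaelis-Menten (``Vm*C/(Km+C)`` with ``Vm = vmkm*Km``) when a
Michaelis constant is supplied.  TFV-DP is eliminated first order (``Kout``).

Amounts are µmol, volumes L, times days, concentrations µM throughout; unit
conversions to assay units (ng/mL, fmol per 1e6 cells) happen only at the
I/O boundary via :class:`MolarConstants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "MolarConstants",
    "MOLAR",
    "PKParameters",
    "IVInfusion",
    "ImplantInput",
    "DosingRegimen",
    "MAT_FLOOR_D",
    "ode_rhs",
    "input_rates",
    "terminal_half_life",
    "steady_state_concentration",
    "SteadyState",
]

# Absorption from the depot is effectively instantaneous (mean absorption
# time under a minute); a floor keeps the ODE system integrable.
MAT_FLOOR_D = 1e-4


@dataclass(frozen=True)
class MolarConstants:
    """Fixed physical constants used at the unit-conversion boundary.

    ``pbmc_cell_volume_ul`` is the mean PBMC cell volume per 1e6 cells, the
    convention under which 1.0 fmol/1e6 cells corresponds to 5.0e-3 µM.
    """

    mw_taf: float = 476.47  # g/mol, TAF free base
    mw_tfv: float = 287.21  # g/mol, tenofovir
    pbmc_cell_volume_ul: float = 0.2  # µL per 1e6 PBMCs

    def plasma_ng_ml_to_uM(self, value):
        """Plasma TFV: ng/mL -> µM (1.0 ng/mL = 3.5e-3 µM)."""
        return np.asarray(value, dtype=float) / self.mw_tfv

    def plasma_uM_to_ng_ml(self, value):
        return np.asarray(value, dtype=float) * self.mw_tfv

    def pbmc_fmol_to_uM(self, value):
        """PBMC TFV-DP: fmol/1e6 cells -> µM (1.0 fmol/1e6 cells = 5.0e-3 µM)."""
        return np.asarray(value, dtype=float) / self.pbmc_cell_volume_ul * 1e-3

    def pbmc_uM_to_fmol(self, value):
        return np.asarray(value, dtype=float) * self.pbmc_cell_volume_ul * 1e3

    def mg_taf_to_umol(self, mg):
        """mg TAF -> µmol TFV-equivalents (1:1 molar hydrolysis)."""
        return np.asarray(mg, dtype=float) / self.mw_taf * 1e3


MOLAR = MolarConstants()


@dataclass
class PKParameters:
    """Systemic TFV/TFV-DP parameter vector.

    Parameters
    ----------
    V : float
        Central volume of distribution of TFV (L).
    Cl : float
        Total body clearance of TFV (L/d).
    Vp, Clp : float
        Peripheral volume (L) and inter-compartmental clearance (L/d).
    MAT : float
        Mean absorption time from the subcutaneous depot (d); the
        first-order absorption rate constant is ``1/max(MAT, 1e-4)``.
    F : float
        Apparent bioavailability of depot input relative to IV dosing;
        dimensionless and may exceed 1 under sustained release.
    Kout : float
        First-order elimination rate constant of PBMC TFV-DP (1/d).
    vmkm : float
        Linearized Michaelis-Menten formation clearance Vm/Km (L/d),
        converting plasma TFV to PBMC TFV-DP.
    Km : float, optional
        Michaelis constant (µM).  When given, formation is saturable with
        ``Vm = vmkm * Km``; when absent the model is strictly linear.
    sigma_plasma, sigma_pbmc : float
        Proportional model-error CVs (fraction of the prediction).
    """

    V: float = 84.7
    Cl: float = 174.0
    Vp: float = 534.0
    Clp: float = 681.0
    MAT: float = 1.0 / 1440.0  # < 1 min, in days
    F: float = 3.4
    Kout: float = 1.84
    vmkm: float = 1.7e-4
    Km: Optional[float] = None
    sigma_plasma: float = 0.746
    sigma_pbmc: float = 1.05

    def __post_init__(self):
        for name in ("V", "Cl", "Vp", "Clp", "F", "Kout", "vmkm",
                     "sigma_plasma", "sigma_pbmc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.MAT < 0:
            raise ValueError("MAT must be non-negative")
        if self.Km is not None and not self.Km > 0:
            raise ValueError("Km, when given, must be strictly positive")

    @property
    def ka(self) -> float:
        """First-order absorption rate constant (1/d), MAT floored at 1e-4 d."""
        return 1.0 / max(self.MAT, MAT_FLOOR_D)

    @property
    def is_linear(self) -> bool:
        return self.Km is None

    def formation_rate(self, conc_uM):
        """TFV -> TFV-DP formation flux (µmol/d) at plasma concentration C (µM)."""
        c = np.asarray(conc_uM, dtype=float)
        if self.Km is None:
            return self.vmkm * c
        vm = self.vmkm * self.Km
        return vm * c / (self.Km + c)

    def with_updates(self, **kwargs) -> "PKParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PKParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class IVInfusion:
    """Constant-rate IV infusion of TAF: ``dose`` mg over ``duration`` days."""

    dose: float  # mg TAF
    duration: float  # d
    start: float = 0.0  # d

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not self.duration > 0:
            raise ValueError("infusion duration must be positive")

    @property
    def stop(self) -> float:
        return self.start + self.duration

    @property
    def rate_mg_d(self) -> float:
        return self.dose / self.duration


@dataclass(frozen=True)
class ImplantInput:
    """Zero-order subcutaneous input from one implant.

    ``rate`` mg TAF/d from ``start`` until ``stop`` (removal), or until the
    optional finite ``load`` (mg) is depleted, whichever comes first.
    """

    rate: float  # mg TAF / d
    start: float  # d
    stop: float  # d (removal)
    load: Optional[float] = None  # mg; None = not depletion-limited

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("release rate must be non-negative")
        if not self.stop > self.start:
            raise ValueError("stop must be after start")
        if self.load is not None and self.load < 0:
            raise ValueError("load must be non-negative")

    @property
    def effective_stop(self) -> float:
        """Removal time, or earlier depletion time for a finite load."""
        if self.load is None or self.rate == 0:
            return self.stop
        return min(self.stop, self.start + self.load / self.rate)


DoseEvent = Union[IVInfusion, ImplantInput]


@dataclass
class DosingRegimen:
    """Per-animal dosing history: IV infusions and/or implant inputs.

    Events may overlap (multiple implants in situ at once).
    """

    events: Sequence[DoseEvent] = field(default_factory=list)
    body_weight: float = 10.0  # kg

    def __post_init__(self):
        if not self.body_weight > 0:
            raise ValueError("body weight must be positive")
        self.events = list(self.events)

    def breakpoints(self) -> np.ndarray:
        """Sorted unique times where the input rate is discontinuous."""
        pts = set()
        for ev in self.events:
            pts.add(ev.start)
            if isinstance(ev, ImplantInput):
                pts.add(ev.effective_stop)
            else:
                pts.add(ev.stop)
        return np.array(sorted(pts), dtype=float)

    def horizon(self) -> float:
        bp = self.breakpoints()
        return float(bp[-1]) if bp.size else 0.0

    def total_dose_mg(self, t: float) -> float:
        """Cumulative TAF administered (mg) up to time t."""
        total = 0.0
        for ev in self.events:
            if isinstance(ev, IVInfusion):
                frac = np.clip((t - ev.start) / ev.duration, 0.0, 1.0)
                total += ev.dose * frac
            else:
                active = np.clip(t, ev.start, ev.effective_stop) - ev.start
                total += ev.rate * max(active, 0.0)
        return total


def input_rates(t: float, regimen: DosingRegimen,
                constants: MolarConstants = MOLAR) -> tuple[float, float]:
    """Instantaneous input rates (µmol/d): (subcutaneous depot, IV central).

    Event intervals are half-open ``[start, stop)`` so that the rate at a
    breakpoint belongs to the segment starting there.
    """
    sc = 0.0
    iv = 0.0
    for ev in regimen.events:
        if isinstance(ev, IVInfusion):
            if ev.start <= t < ev.stop:
                iv += ev.rate_mg_d
        else:
            if ev.start <= t < ev.effective_stop:
                sc += ev.rate
    return constants.mg_taf_to_umol(sc), constants.mg_taf_to_umol(iv)


def ode_rhs(t: float, state, params: PKParameters, regimen: DosingRegimen,
            constants: MolarConstants = MOLAR) -> np.ndarray:
    """Right-hand side of the model ODEs; ``state`` is (A_depot, A_c, A_p, A_dp) µmol.

    Mass bookkeeping: the sum of the derivatives plus the elimination fluxes
    ``(Cl/V)*A_c + Kout*A_dp + (1-F)*ka*A_depot`` equals the total input
    rate at time t.
    """
    state = np.asarray(state, dtype=float)
    if state[:4].min() < -1e-9:
        raise ValueError(f"negative state at t={t}: {state[:4]}")
    a_depot, a_c, a_p, a_dp = state[:4]
    sc_in, iv_in = input_rates(t, regimen, constants)

    ka = params.ka
    c = a_c / params.V  # µM
    form = float(params.formation_rate(c))
    k10 = params.Cl / params.V
    k12 = params.Clp / params.V
    k21 = params.Clp / params.Vp

    d_depot = sc_in - ka * a_depot
    d_c = params.F * ka * a_depot + iv_in - k10 * a_c - k12 * a_c + k21 * a_p - form
    d_p = k12 * a_c - k21 * a_p
    d_dp = form - params.Kout * a_dp
    return np.array([d_depot, d_c, d_p, d_dp])


def terminal_half_life(params: PKParameters) -> float:
    """Terminal (beta-phase) half-life of plasma TFV, in hours.

    Uses the slow eigenvalue of the two-compartment disposition matrix:
    with k10 = Cl/V, k12 = Clp/V, k21 = Clp/Vp,

        beta = 0.5 * [(k10+k12+k21) - sqrt((k10+k12+k21)^2 - 4 k10 k21)]

    and t_1/2 = ln(2)/beta.  Valid for the linear model only.

    With negligible inter-compartmental clearance the slow eigenvalue tends
    to k21 but carries no mass (zero residue in the plasma profile); the
    observable terminal slope is then k10 and the one-compartment value
    ln(2)*V/Cl is returned.
    """
    k10 = params.Cl / params.V
    k12 = params.Clp / params.V
    k21 = params.Clp / params.Vp
    if max(k12, k21) < 1e-9 * k10:  # one-compartment limit
        return math.log(2.0) / k10 * 24.0
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    # disc >= (k10 - k21)^2 >= 0 algebraically; guard rounding
    beta = 0.5 * (s - math.sqrt(max(disc, 0.0)))
    return math.log(2.0) / beta * 24.0


@dataclass(frozen=True)
class SteadyState:
    """Closed-form steady state of the linear model under constant input."""

    plasma_uM: float
    plasma_ng_ml: float
    pbmc_uM: float
    pbmc_fmol_per_1e6: float


def steady_state_concentration(params: PKParameters, rate_mg_d: float,
                               constants: MolarConstants = MOLAR) -> SteadyState:
    """Unique steady state under a constant subcutaneous input (linear model).

    At steady state the absorbed input ``F * Rin`` (µmol/d) balances central
    elimination plus formation: ``Css = F*Rin / (Cl + vmkm)``, and the
    TFV-DP level balances formation against ``Kout``.

    Raises for the saturable mode, where no closed form is guaranteed.
    """
    if not params.is_linear:
        raise ValueError("closed-form steady state requires the linear model")
    if rate_mg_d < 0:
        raise ValueError("rate must be non-negative")
    rin = constants.mg_taf_to_umol(rate_mg_d)  # µmol/d
    css = params.F * rin / (params.Cl + params.vmkm)  # µM
    # PBMC compartment volume fixed to 1 L-equivalent internally
    a_dp = params.vmkm * css / params.Kout  # µmol
    dp_uM = a_dp / 1.0
    return SteadyState(
        plasma_uM=css,
        plasma_ng_ml=float(constants.plasma_uM_to_ng_ml(css)),
        pbmc_uM=dp_uM,
        pbmc_fmol_per_1e6=float(constants.pbmc_uM_to_fmol(dp_uM)),
    )
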