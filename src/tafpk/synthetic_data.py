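"""Virtual TAF implant / IV studies with the statistical structure the
analysis assumes.

Each virtual animal gets a body weight, per-implant release rates drawn
lognormally around the design rate, a noise-free profile simulated from the
true parameters, multiplicative lognormal proportional noise at the
matrix-specific CVs, and LLOQ censoring with flags.  A truth ledger records
every latent value so estimator recovery can be scored exactly.

One global seed fans out to per-animal substreams (``SeedSequence`` spawn
keys), so adding an animal never perturbs the data of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimate import ObservationSet
from .model_core import DosingRegimen, IVInfusion, ImplantInput, PKParameters
from .release_kinetics import ImplantRecord
from .simulate import simulate_profile

__all__ = [
    "DOG_IMPLANT_SCHEDULE_D",
    "DOG_IV_SCHEDULE_D",
    "MOUSE_SACRIFICE_DAYS",
    "GroupDesign",
    "StudyDesign",
    "SyntheticStudy",
    "generate_study",
    "generate_release_series",
    "write_study",
]

# Beagle-dog implant study: samples on Day 1 (0.5, 6, 24 h) then Days 2-37;
# implants placed Day 0 and removed Day 30.
DOG_IMPLANT_SCHEDULE_D = tuple(
    [0.5 / 24, 6.0 / 24, 1.0, 2.0, 4.0, 7.0, 10.0, 14.0, 21.0, 30.0,
     31.0, 33.0, 35.0, 37.0]
)

# IV study: rich early sampling (0.25-24 h) then daily through Day 7.
DOG_IV_SCHEDULE_D = tuple(
    sorted([h / 24 for h in (0.25, 0.5, 0.75, 1, 2, 4, 6, 12, 24)]
           + [2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
)

# Mouse serial-sacrifice days
MOUSE_SACRIFICE_DAYS = (3.0, 7.0, 14.0, 21.0, 28.0)

_SPECIES_WEIGHTS = {  # (mean kg, CV)
    "dog": (10.5, 0.12),
    "mouse": (0.025, 0.10),
    "sheep": (60.0, 0.15),
}


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass
class GroupDesign:
    """One study arm: implant count/placement and its true bioavailability."""

    name: str
    n_animals: int
    n_implants: int = 1
    n_pockets: int = 1
    true_F: float = 9.6
    true_vmkm: Optional[float] = None  # default: StudyDesign.params.vmkm

    def __post_init__(self):
        if self.n_animals < 1 or self.n_implants < 0:
            raise ValueError("invalid group size")
        if self.n_pockets < 1 or self.n_pockets > max(self.n_implants, 1):
            raise ValueError("pockets must be between 1 and the implant count")


@dataclass
class StudyDesign:
    """Everything needed to generate one virtual study deterministically."""

    study: str = "synthetic"
    species: str = "dog"
    kind: str = "implant"  # implant | iv
    groups: Sequence[GroupDesign] = field(
        default_factory=lambda: [GroupDesign("single", 4)])
    params: PKParameters = field(default_factory=PKParameters)
    mean_rate_mg_d: float = 2.1  # per-implant in vivo release rate
    rate_cv: float = 0.30  # inter-implant lognormal spread
    # True TFV->TFV-DP formation clearance (L/d) on the internal scale where
    # the PBMC compartment is 1 L-equivalent.  The absolute value is a
    # convention tied to that scale; 2.0 L/d puts simulated TFV-DP one to
    # two orders of magnitude above the assay LLOQ (as observed in dogs)
    # while staying ~100x below Cl, keeping formation a negligible
    # clearance pathway.
    true_vmkm: float = 2.0
    implant_load_mg: float = 120.0
    implant_days: tuple = (0.0, 30.0)  # placement, removal
    iv_dose_mg_per_kg: float = 1.0
    iv_infusion_d: float = 30.0 / 1440.0
    schedule_d: Optional[Sequence[float]] = None
    noise_cv_plasma: Optional[float] = None  # default: params.sigma_plasma
    noise_cv_pbmc: Optional[float] = None  # default: params.sigma_pbmc
    lloq_plasma: float = 1.0  # ng/mL
    lloq_pbmc: float = 5.0  # fmol/1e6 cells
    seed: int = 0

    def __post_init__(self):
        if self.species not in _SPECIES_WEIGHTS:
            raise ValueError(f"unknown species {self.species!r}")
        if self.kind not in ("implant", "iv"):
            raise ValueError("kind must be 'implant' or 'iv'")
        for cv in (self.noise_cv_plasma, self.noise_cv_pbmc, self.rate_cv):
            if cv is not None and cv < 0:
                raise ValueError("CVs must be non-negative")
        if self.mean_rate_mg_d < 0 or self.implant_load_mg <= 0:
            raise ValueError("invalid implant design")

    @property
    def cv_plasma(self) -> float:
        return (self.params.sigma_plasma if self.noise_cv_plasma is None
                else self.noise_cv_plasma)

    @property
    def cv_pbmc(self) -> float:
        return (self.params.sigma_pbmc if self.noise_cv_pbmc is None
                else self.noise_cv_pbmc)

    @property
    def times(self) -> np.ndarray:
        if self.schedule_d is not None:
            return np.asarray(self.schedule_d, dtype=float)
        if self.kind == "iv":
            return np.asarray(DOG_IV_SCHEDULE_D)
        if self.species == "mouse":
            return np.asarray(MOUSE_SACRIFICE_DAYS)
        return np.asarray(DOG_IMPLANT_SCHEDULE_D)


@dataclass
class SyntheticStudy:
    """Generated dataset plus its ground-truth ledger."""

    observations: pd.DataFrame
    regimens: dict
    implants: list
    truth: dict
    study: str = "synthetic"

    def observation_set(self) -> ObservationSet:
        return ObservationSet(data=self.observations, regimens=self.regimens,
                              study=self.study)


def generate_study(design: StudyDesign) -> SyntheticStudy:
    """Generate one virtual study; the seed fixes the dataset bit-for-bit."""
    sig_pl = _lognormal_sigma(design.cv_plasma)
    sig_dp = _lognormal_sigma(design.cv_pbmc)
    w_mean, w_cv = _SPECIES_WEIGHTS[design.species]
    sig_w = _lognormal_sigma(w_cv)
    sig_rate = _lognormal_sigma(design.rate_cv)
    times = design.times
    place, remove = design.implant_days

    rows = []
    regimens: dict[str, DosingRegimen] = {}
    implants: list[ImplantRecord] = []
    truth: dict = {"design_seed": design.seed, "animals": {}}

    animal_idx = 0
    for group in design.groups:
        vmkm_true = (group.true_vmkm if group.true_vmkm is not None
                     else design.true_vmkm)
        for _ in range(group.n_animals):
            rng = np.random.default_rng(
                np.random.SeedSequence(design.seed, spawn_key=(animal_idx,)))
            animal = f"{design.study}-{animal_idx:03d}"
            weight = w_mean * float(np.exp(rng.normal(0.0, sig_w)))
            p_true = design.params.with_updates(F=group.true_F, vmkm=vmkm_true)

            if design.kind == "iv":
                events = [IVInfusion(dose=design.iv_dose_mg_per_kg * weight,
                                     duration=design.iv_infusion_d, start=0.0)]
                rates = []
            else:
                rates = [design.mean_rate_mg_d
                         * float(np.exp(rng.normal(0.0, sig_rate)))
                         for _ in range(group.n_implants)]
                events = [ImplantInput(rate=r, start=place, stop=remove,
                                       load=design.implant_load_mg)
                          for r in rates]
                for j, r in enumerate(rates):
                    days = remove - place
                    released = min(r * days, design.implant_load_mg)
                    implants.append(ImplantRecord(
                        study=design.study, animal=animal,
                        pocket=str(1 + j % group.n_pockets),
                        initial_load=design.implant_load_mg,
                        residual=design.implant_load_mg - released,
                        days_in_situ=days, recovered=True,
                    ))
            regimen = DosingRegimen(events=events, body_weight=weight)
            regimens[animal] = regimen

            sim = simulate_profile(p_true, regimen, times)
            for mat, clean, lloq, sig in (
                    ("plasma_tfv", sim.plasma_tfv_ng_ml, design.lloq_plasma,
                     sig_pl),
                    ("pbmc_tfvdp", sim.pbmc_tfvdp_fmol_per_1e6,
                     design.lloq_pbmc, sig_dp)):
                # mean-preserving lognormal: E[noise]=1, CV as designed,
                # matching the proportional-error observation model y=f(1+eps)
                noise = (np.exp(rng.normal(-0.5 * sig**2, sig,
                                           size=times.size))
                         if sig > 0 else np.ones(times.size))
                obs = clean * noise
                for t, v in zip(times, obs):
                    bloq = bool(v < lloq)
                    rows.append({
                        "study": design.study, "animal": animal,
                        "group": group.name, "matrix": mat,
                        "time_d": float(t),
                        "value": (np.nan if bloq else float(v)),
                        "lloq": lloq, "bloq": int(bloq), "is_bloq": bloq,
                    })
            truth["animals"][animal] = {
                "group": group.name, "weight_kg": weight, "F": group.true_F,
                "vmkm": vmkm_true, "rates_mg_d": rates,
            }
            animal_idx += 1

    observations = pd.DataFrame(rows)
    return SyntheticStudy(observations=observations, regimens=regimens,
                          implants=implants, truth=truth, study=design.study)


def generate_release_series(
    true_rate: float,
    load: float,
    schedule: Sequence[float] = MOUSE_SACRIFICE_DAYS,
    residual_noise_sd: float = 0.0,
    n_per_timepoint: int = 3,
    dropout_p: float = 0.0,
    seed: int = 0,
    allow_depletion: bool = False,
    study: str = "synthetic-release",
) -> list[ImplantRecord]:
    """Serial-sacrifice implant records under zero-order release.

    Residual = load - rate*t + Normal(0, sd), truncated to [0, load];
    each sacrificed animal's implant may be missing with ``dropout_p``.
    Raises when the schedule would deplete the load, unless
    ``allow_depletion`` is set.
    """
    schedule = list(schedule)
    if not schedule:
        raise ValueError("schedule must be non-empty")
    if true_rate < 0 or load <= 0:
        raise ValueError("need a non-negative rate and positive load")
    if true_rate * max(schedule) > load and not allow_depletion:
        raise ValueError(
            "release schedule exhausts the implant load; pass "
            "allow_depletion=True to truncate at zero residual")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    k = 0
    for day in schedule:
        for _ in range(n_per_timepoint):
            missing = bool(rng.random() < dropout_p)
            residual = float(np.clip(
                load - true_rate * day + rng.normal(0.0, residual_noise_sd),
                0.0, load))
            records.append(ImplantRecord(
                study=study, animal=f"m{k:03d}",
                initial_load=load,
                residual=None if missing else residual,
                days_in_situ=day, length=10.0, outer_diameter=2.4,
                recovered=not missing,
            ))
            k += 1
    return records


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write observations.csv, regimens.csv, implants.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    obs = study.observations.drop(columns=["is_bloq"])
    paths["observations"] = outdir / "observations.csv"
    obs.to_csv(paths["observations"], index=False)

    reg_rows = []
    for animal, reg in study.regimens.items():
        for ev in reg.events:
            if isinstance(ev, IVInfusion):
                reg_rows.append({
                    "animal": animal, "event_type": "iv_infusion",
                    "start_d": ev.start, "stop_d": ev.stop,
                    "rate_mg_d": "", "dose_mg": ev.dose, "load_mg": "",
                    "body_weight_kg": reg.body_weight})
            else:
                reg_rows.append({
                    "animal": animal, "event_type": "implant",
                    "start_d": ev.start, "stop_d": ev.stop,
                    "rate_mg_d": ev.rate, "dose_mg": "",
                    "load_mg": "" if ev.load is None else ev.load,
                    "body_weight_kg": reg.body_weight})
    paths["regimens"] = outdir / "regimens.csv"
    pd.DataFrame(reg_rows).to_csv(paths["regimens"], index=False)

    imp_rows = [{
        "study": r.study, "animal": r.animal, "pocket": r.pocket,
        "length_mm": r.length, "n_orifices": r.n_orifices,
        "orifice_d_mm": r.orifice_diameter, "load_mg": r.initial_load,
        "residual_mg": "" if r.residual is None else r.residual,
        "days": r.days_in_situ, "recovered": int(r.recovered),
    } for r in study.implants]
    paths["implants"] = outdir / "implants.csv"
    pd.DataFrame(imp_rows).to_csv(paths["implants"], index=False)

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(study.truth, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
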