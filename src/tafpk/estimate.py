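"""Extended-least-squares (ELS) parameter estimation with proportional error.

The observation model is ``y = f(theta) * (1 + eps)`` with matrix-specific
proportional error CV ``sigma_m`` (plasma TFV and PBMC TFV-DP are fitted on
their assay scales; the proportional objective is scale-invariant within a
matrix).  The ELS objective

    O(theta) = sum_i [ (y_i - f_i)^2 / (sigma_m(i)^2 f_i^2)
                       + ln(sigma_m(i)^2 f_i^2) ]

equals -2 x the Gaussian log-likelihood with variance ``sigma^2 f^2`` up to
the additive constant ``n ln(2 pi)``.  Error CVs may be fixed or profiled
out analytically (``sigma_m^2 = mean(((y - f)/f)^2)`` at the optimum).

Fitting is per animal by default — systemic parameters fixed from IV/implant
co-modeling, apparent bioavailability F and the formation clearance Vm/Km
free per animal — with group-level sharing and joint refinement of the
systemic parameters available through :func:`comodel`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model_core import DosingRegimen, IVInfusion, PKParameters
from .simulate import simulate_profile

__all__ = [
    "ObservationSet",
    "FitResult",
    "ComodelResult",
    "els_objective",
    "predict_observations",
    "fit_animal",
    "comodel",
    "summarize_group",
]

FITTABLE_MATRICES = ("plasma_tfv", "pbmc_tfvdp")

# systemic (structural) parameters that may be shared across animals
SYSTEMIC_NAMES = ("V", "Cl", "Vp", "Clp", "MAT", "Kout")

# relative solver tolerance used inside optimization loops; final reported
# objectives are recomputed at the tighter simulation default
_FIT_RTOL = 1e-7
_FIT_ATOL = 1e-9


@dataclass
class ObservationSet:
    """Observed concentration records plus each animal's dosing regimen.

    ``data`` columns: animal, group, matrix, time_d, value, lloq, is_bloq
    (a ``study`` column is optional).  Every animal in ``data`` must have an
    entry in ``regimens``.
    """

    data: pd.DataFrame
    regimens: dict[str, DosingRegimen]
    study: str = ""

    def __post_init__(self):
        required = {"animal", "group", "matrix", "time_d", "value", "lloq",
                    "is_bloq"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"observation data missing columns: {sorted(missing)}")
        orphans = set(self.data["animal"].unique()) - set(self.regimens)
        if orphans:
            raise ValueError(f"animals without a regimen: {sorted(orphans)}")
        if (self.data["time_d"] < 0).any():
            raise ValueError("observation times must be non-negative")
        ok = self.data["is_bloq"] | (self.data["value"] > 0)
        if not ok.all():
            raise ValueError("non-BLQ observations must be strictly positive")

    @property
    def animals(self) -> list[str]:
        return sorted(self.data["animal"].unique())

    def group_of(self, animal: str) -> str:
        return str(self.data.loc[self.data["animal"] == animal, "group"].iloc[0])

    def has_iv_anchor(self) -> bool:
        return any(
            isinstance(ev, IVInfusion)
            for reg in self.regimens.values() for ev in reg.events
        )


def els_objective(y, f, sigma) -> float:
    """Extended-least-squares objective for proportional error.

    ``sigma`` is the proportional error CV, a scalar or a per-record array
    (use the latter to mix matrices).  All predictions must be strictly
    positive — the proportional variance is undefined at f = 0.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), f.shape)
    if f.size and f.min() <= 0:
        raise ValueError("ELS requires strictly positive predictions")
    if sigma.size and sigma.min() <= 0:
        raise ValueError("sigma must be strictly positive")
    var = sigma**2 * f**2
    return float(np.sum((y - f) ** 2 / var + np.log(var)))


def _els_profiled(y, f, matrix_idx, n_matrices) -> tuple[float, np.ndarray]:
    """ELS with the per-matrix sigma^2 profiled out analytically.

    Returns (objective, sigma_hat per matrix).
    """
    if f.min() <= 0:
        raise ValueError("ELS requires strictly positive predictions")
    r2 = ((y - f) / f) ** 2
    total = float(np.sum(np.log(f**2)))
    sig = np.full(n_matrices, np.nan)
    for m in range(n_matrices):
        mask = matrix_idx == m
        n_m = int(mask.sum())
        if n_m == 0:
            continue
        s2 = float(r2[mask].mean())
        s2 = max(s2, 1e-12)  # guard exact-fit degeneracy
        sig[m] = np.sqrt(s2)
        total += n_m * (1.0 + np.log(s2))
    return total, sig


def predict_observations(params: PKParameters, regimen: DosingRegimen,
                         obs: pd.DataFrame, rtol=_FIT_RTOL, atol=_FIT_ATOL,
                         ) -> np.ndarray:
    """Model predictions matched to observation records, on assay scales
    (plasma TFV ng/mL; PBMC TFV-DP fmol/1e6 cells)."""
    bad = set(obs["matrix"].unique()) - set(FITTABLE_MATRICES)
    if bad:
        raise ValueError(f"matrices not supported by the systemic model: {sorted(bad)}")
    times = np.unique(obs["time_d"].to_numpy(dtype=float))
    sim = simulate_profile(params, regimen, times, rtol=rtol, atol=atol)
    plasma = dict(zip(times, sim.plasma_tfv_ng_ml))
    pbmc = dict(zip(times, sim.pbmc_tfvdp_fmol_per_1e6))
    out = np.empty(len(obs))
    for i, (mat, t) in enumerate(zip(obs["matrix"], obs["time_d"])):
        out[i] = plasma[t] if mat == "plasma_tfv" else pbmc[t]
    return out


@dataclass
class FitResult:
    """Outcome of one ELS minimization."""

    estimates: PKParameters
    free: tuple
    objective: float
    cv_percent: dict
    sigma: dict
    converged: bool
    n_evals: int
    starts: list = field(default_factory=list)
    message: str = ""
    animal: str = ""
    group: str = ""

    def param(self, name: str) -> float:
        return getattr(self.estimates, name)


def _prepare_obs(obs: pd.DataFrame, include_bloq: bool) -> pd.DataFrame:
    obs = obs.copy()
    if include_bloq:
        bloq = obs["is_bloq"].astype(bool)
        obs.loc[bloq, "value"] = obs.loc[bloq, "lloq"] / 2.0
    else:
        obs = obs[~obs["is_bloq"].astype(bool)]
    return obs.sort_values(["matrix", "time_d"], kind="mergesort").reset_index(drop=True)


class _LinearScalingPredictor:
    """Fast exact predictor for free parameters within {F, vmkm}.

    With the systemic parameters fixed and the linear formation term, plasma
    TFV is proportional to F and PBMC TFV-DP to F * vmkm, once the (tiny)
    formation loss from the central compartment is folded in at its
    reference value (vmkm is ~6 orders of magnitude below Cl, so the folding
    error is ~1e-6 relative).  One base simulation then serves every
    objective evaluation.
    """

    def __init__(self, params: PKParameters, regimen: DosingRegimen,
                 obs: pd.DataFrame):
        self.ref_F = params.F
        self.ref_vmkm = params.vmkm
        base = predict_observations(params, regimen, obs)
        self.is_plasma = (obs["matrix"] == "plasma_tfv").to_numpy()
        self.base = base

    def __call__(self, F: float, vmkm: float) -> np.ndarray:
        scale = np.where(self.is_plasma, F / self.ref_F,
                         (F / self.ref_F) * (vmkm / self.ref_vmkm))
        return self.base * scale


def _num_hessian(fun, x, h=1e-4):
    n = len(x)
    hess = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                val = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h**2
            else:
                val = (fun(x + ei + ej) - fun(x + ei - ej)
                       - fun(x - ei + ej) + fun(x - ei - ej)) / (4 * h**2)
            hess[i, j] = hess[j, i] = val
    return hess


def _cv_from_hessian(fun, theta_opt, names):
    """Approximate CV% of each estimate from the curvature of the objective.

    The ELS objective is -2 log L up to a constant, so the covariance of the
    log-scale estimates is ~ 2 H^-1; on the log scale the standard error is
    directly a coefficient of variation.
    """
    try:
        hess = _num_hessian(fun, theta_opt)
        cov = 2.0 * np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive curvature")
        return {n: 100.0 * float(np.sqrt(d)) for n, d in zip(names, diag)}
    except np.linalg.LinAlgError:
        return {n: float("nan") for n in names}


_START_SCALES = (1.0, 0.2, 5.0)


def fit_animal(
    obs: pd.DataFrame,
    regimen: DosingRegimen,
    init: PKParameters,
    free: Sequence[str] = ("F", "vmkm"),
    include_bloq: bool = False,
    estimate_sigma: bool = True,
    n_starts: int = 3,
    fast: Optional[bool] = None,
    animal: str = "",
    group: str = "",
) -> FitResult:
    """Fit the free parameters for one animal by ELS.

    Parameters are log-transformed for positivity and the optimizer is run
    from ``n_starts`` default starting points (the initial values scaled by
    1x, 0.2x, 5x); the best optimum wins, ties broken by the smallest
    log-parameter vector.  BLQ records are excluded by default (LLOQ/2
    inclusion behind ``include_bloq``).  Error CVs are profiled out unless
    ``estimate_sigma=False``, which fixes them at the values in ``init``.

    ``fast=None`` auto-selects an exact scaling shortcut when only F and/or
    vmkm are free and the model is linear.
    """
    free = tuple(free)
    unknown = [p for p in free if not hasattr(init, p)]
    if unknown:
        raise ValueError(f"unknown free parameters: {unknown}")
    obs = _prepare_obs(obs, include_bloq)
    if len(obs) < len(free):
        raise ValueError(
            f"{len(obs)} informative observations cannot identify "
            f"{len(free)} free parameters")
    if fast is None:
        fast = set(free) <= {"F", "vmkm"} and init.is_linear

    matrices = sorted(obs["matrix"].unique())
    matrix_idx = obs["matrix"].map({m: i for i, m in enumerate(matrices)}).to_numpy()
    y = obs["value"].to_numpy(dtype=float)
    sigma_fixed = np.array(
        [init.sigma_plasma if m == "plasma_tfv" else init.sigma_pbmc
         for m in obs["matrix"]])

    if fast:
        predictor = _LinearScalingPredictor(init, regimen, obs)

        def predictions(theta):
            p = dict(zip(free, np.exp(theta)))
            return predictor(p.get("F", init.F), p.get("vmkm", init.vmkm))
    else:
        def predictions(theta):
            updates = dict(zip(free, np.exp(theta)))
            params = init.with_updates(**updates)
            return predict_observations(params, regimen, obs)

    n_evals = [0]

    def objective(theta):
        n_evals[0] += 1
        try:
            f = predictions(theta)
            if estimate_sigma:
                val, _ = _els_profiled(y, f, matrix_idx, len(matrices))
            else:
                val = els_objective(y, f, sigma_fixed)
        except (ValueError, RuntimeError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    theta0 = np.log([getattr(init, p) for p in free])
    starts_log = []
    best = None
    for scale in _START_SCALES[:n_starts]:
        start = theta0 + np.log(scale)
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-10,
                                "maxiter": 400 * len(free)})
        res = minimize(objective, res.x, method="L-BFGS-B",
                       options={"maxiter": 200})
        starts_log.append({"start": np.exp(start).tolist(),
                           "objective": float(res.fun),
                           "success": bool(res.success)})
        cand = (float(res.fun), tuple(res.x), res)
        if best is None or cand[0] < best[0] - 1e-12 or (
                abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]):
            best = cand
    obj_val, theta_opt, res = best
    theta_opt = np.asarray(theta_opt)
    converged = bool(np.isfinite(obj_val) and obj_val < 1e11)
    if not converged:
        warnings.warn(f"fit for animal {animal or '?'} did not converge",
                      stacklevel=2)

    f_opt = predictions(theta_opt)
    if estimate_sigma:
        _, sig_hat = _els_profiled(y, f_opt, matrix_idx, len(matrices))
        sigma_out = dict(zip(matrices, sig_hat))
    else:
        sigma_out = {m: (init.sigma_plasma if m == "plasma_tfv"
                         else init.sigma_pbmc) for m in matrices}

    updates = dict(zip(free, np.exp(theta_opt)))
    if "plasma_tfv" in sigma_out and np.isfinite(sigma_out["plasma_tfv"]):
        updates["sigma_plasma"] = max(sigma_out["plasma_tfv"], 1e-6)
    if "pbmc_tfvdp" in sigma_out and np.isfinite(sigma_out["pbmc_tfvdp"]):
        updates["sigma_pbmc"] = max(sigma_out["pbmc_tfvdp"], 1e-6)
    estimates = init.with_updates(**updates)
    cv = _cv_from_hessian(objective, theta_opt, free) if converged else {
        p: float("nan") for p in free}

    return FitResult(
        estimates=estimates, free=free, objective=obj_val, cv_percent=cv,
        sigma=sigma_out, converged=converged, n_evals=n_evals[0],
        starts=starts_log, message=str(getattr(res, "message", "")),
        animal=animal, group=group,
    )


def summarize_group(fits: Sequence[FitResult],
                    params: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-parameter summary across fits: mean, CV% (100*SD/mean, sample SD),
    median, min, max.  CV is not applicable (NaN) for a single fit."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to summarize")
    if params is None:
        params = fits[0].free
    rows = {}
    for p in params:
        vals = np.array([f.param(p) for f in fits], dtype=float)
        mean = float(vals.mean())
        cv = (100.0 * float(vals.std(ddof=1)) / mean
              if len(vals) > 1 and mean != 0 else float("nan"))
        rows[p] = {"n": len(vals), "mean": mean, "cv_percent": cv,
                   "median": float(np.median(vals)),
                   "min": float(vals.min()), "max": float(vals.max())}
    return pd.DataFrame(rows).T


@dataclass
class ComodelResult:
    """Joint IV + implant fit: shared systemic parameters plus per-animal
    (and per-group) apparent bioavailability and formation clearance."""

    shared: PKParameters
    animal_fits: dict
    group_summaries: dict
    objective: float
    n_outer: int
    converged: bool

    def summary_frame(self) -> pd.DataFrame:
        frames = []
        for g, df in self.group_summaries.items():
            d = df.copy()
            d.insert(0, "group", g)
            frames.append(d.rename_axis("parameter").reset_index())
        return pd.concat(frames, ignore_index=True)


def _total_objective(shared, animal_params, obs_by_animal, regimens,
                     sigma_map_fn, estimate_sigma):
    """Pooled ELS over all animals at the current parameter values, with
    sigma profiled globally per matrix when co-estimated."""
    ys, fs, mats = [], [], []
    for animal, obs in obs_by_animal.items():
        params = animal_params[animal]
        f = predict_observations(params, regimens[animal], obs)
        ys.append(obs["value"].to_numpy(dtype=float))
        fs.append(f)
        mats.append(obs["matrix"].to_numpy())
    y = np.concatenate(ys)
    f = np.concatenate(fs)
    mat = np.concatenate(mats)
    matrices = sorted(np.unique(mat))
    idx = np.array([matrices.index(m) for m in mat])
    if estimate_sigma:
        val, sig = _els_profiled(y, f, idx, len(matrices))
        return val, dict(zip(matrices, sig))
    sigma = np.array([sigma_map_fn(m) for m in mat])
    return els_objective(y, f, sigma), None


def comodel(
    studies: Sequence[ObservationSet],
    init: PKParameters,
    shared: Sequence[str] = (),
    animal_level: Sequence[str] = ("F", "vmkm"),
    include_bloq: bool = False,
    estimate_sigma: bool = True,
    max_outer: int = 10,
    tol: float = 1e-6,
) -> ComodelResult:
    """Co-model several studies: shared systemic parameters anchored by IV
    dosing, with F and/or vmkm estimated per animal and summarized per group.

    Alternates (a) per-animal fits of ``animal_level`` parameters with the
    systemic parameters fixed and (b) a pooled refinement of the ``shared``
    systemic subset with the animal-level parameters fixed, until the pooled
    objective changes by less than ``tol`` (relative, on objectives above 1
    in magnitude).  With ``shared=()`` the systemic
    parameters stay at ``init`` (one pass of per-animal fits).

    Raises if systemic parameters are requested free without any IV-dosed
    animal to anchor them.
    """
    shared = tuple(shared)
    animal_level = tuple(animal_level)
    bad = set(shared) - set(SYSTEMIC_NAMES) - {"vmkm", "F"}
    if bad:
        raise ValueError(f"not systemic parameters: {sorted(bad)}")
    if shared and not any(s.has_iv_anchor() for s in studies):
        raise ValueError(
            "co-modeling systemic parameters requires at least one study "
            "with IV dosing to anchor them")

    obs_by_animal: dict[str, pd.DataFrame] = {}
    regimens: dict[str, DosingRegimen] = {}
    group_of: dict[str, str] = {}
    for s in studies:
        for animal in s.animals:
            key = f"{s.study}:{animal}" if s.study else animal
            if key in obs_by_animal:
                raise ValueError(f"duplicate animal id {key}")
            sub = _prepare_obs(s.data[s.data["animal"] == animal], include_bloq)
            if sub.empty:
                continue
            obs_by_animal[key] = sub
            regimens[key] = s.regimens[animal]
            group_of[key] = s.group_of(animal)

    def is_iv_only(key):
        return all(isinstance(ev, IVInfusion) for ev in regimens[key].events)

    current = init
    animal_params = {a: init for a in obs_by_animal}
    animal_fits: dict[str, FitResult] = {}
    prev_obj = np.inf
    converged = False
    n_outer = 0

    for n_outer in range(1, max_outer + 1):
        # (a) per-animal fits; F is inert for IV-only animals (no depot input)
        for key, obs in obs_by_animal.items():
            free = tuple(p for p in animal_level
                         if not (p == "F" and is_iv_only(key)))
            if not free:
                animal_params[key] = current
                continue
            if key in animal_fits:  # warm start from the previous pass
                start = current.with_updates(
                    **{p: animal_fits[key].param(p) for p in free})
                starts = 1
            else:
                start = current
                starts = 3
            fit = fit_animal(obs, regimens[key], start, free=free,
                             include_bloq=False, estimate_sigma=estimate_sigma,
                             n_starts=starts, animal=key, group=group_of[key])
            animal_fits[key] = fit
            animal_params[key] = current.with_updates(
                **{p: fit.param(p) for p in free})

        # (b) pooled refinement of shared systemic parameters
        if shared:
            def pooled(theta):
                updates = dict(zip(shared, np.exp(theta)))
                try:
                    params_map = {
                        a: animal_params[a].with_updates(**updates)
                        for a in obs_by_animal
                    }
                    val, _ = _total_objective(
                        None, params_map, obs_by_animal, regimens,
                        lambda m: (current.sigma_plasma if m == "plasma_tfv"
                                   else current.sigma_pbmc), estimate_sigma)
                except (ValueError, RuntimeError):
                    return 1e12
                return val

            theta0 = np.log([getattr(current, p) for p in shared])
            res = minimize(pooled, theta0, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-9,
                                    "maxiter": 150 * len(shared)})
            updates = dict(zip(shared, np.exp(res.x)))
            current = current.with_updates(**updates)
            animal_params = {a: p.with_updates(**updates)
                             for a, p in animal_params.items()}

        obj, sig = _total_objective(
            None, animal_params, obs_by_animal, regimens,
            lambda m: (current.sigma_plasma if m == "plasma_tfv"
                       else current.sigma_pbmc), estimate_sigma)
        if sig:
            su = {}
            if "plasma_tfv" in sig and np.isfinite(sig["plasma_tfv"]):
                su["sigma_plasma"] = max(sig["plasma_tfv"], 1e-6)
            if "pbmc_tfvdp" in sig and np.isfinite(sig["pbmc_tfvdp"]):
                su["sigma_pbmc"] = max(sig["pbmc_tfvdp"], 1e-6)
            current = current.with_updates(**su)
        if abs(prev_obj - obj) < tol * max(1.0, abs(obj)):
            converged = True
            break
        prev_obj = obj
        if not shared:
            converged = True
            break

    group_summaries = {}
    for g in sorted(set(group_of.values())):
        fits = [f for f in animal_fits.values() if f.group == g]
        if fits:
            group_summaries[g] = summarize_group(fits)

    return ComodelResult(
        shared=current, animal_fits=animal_fits,
        group_summaries=group_summaries, objective=float(obj),
        n_outer=n_outer, converged=converged,
    )
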