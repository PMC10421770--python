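"""ELS objective, per-animal fitting, co-modeling, group summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from tafpk import (
    ObservationSet,
    PKParameters,
    comodel,
    els_objective,
    fit_animal,
    predict_observations,
    summarize_group,
)
from tafpk.synthetic_data import GroupDesign, StudyDesign, generate_study


@pytest.fixture
def fit_init():
    """Order-of-magnitude starting values for per-animal fitting."""
    return PKParameters(F=3.4, vmkm=1.0)


def _one_animal(design):
    study = generate_study(design)
    animal = study.observations["animal"].iloc[0]
    sub = study.observations[study.observations["animal"] == animal]
    return sub, study.regimens[animal], study


class TestElsObjective:
    def test_zero_residual_leaves_log_variance_term(self):
        f = np.array([2.0, 5.0, 9.0])
        sigma = 0.4
        expected = float(np.sum(np.log(sigma**2 * f**2)))
        assert els_objective(f, f, sigma) == pytest.approx(expected, rel=1e-12)

    def test_hand_expanded_two_point_case(self):
        """y=(10,20), f=(10,10), sigma=0.5: first term ln(25); second term
        (20-10)^2/25 + ln(25) = 4 + ln 25."""
        val = els_objective([10.0, 20.0], [10.0, 10.0], 0.5)
        assert val == pytest.approx(4.0 + 2.0 * math.log(25.0), rel=1e-12)

    def test_scaling_data_and_predictions_shifts_by_2n_log10(self):
        y = np.array([3.0, 8.0, 14.0, 2.0])
        f = np.array([4.0, 7.0, 12.0, 2.5])
        base = els_objective(y, f, 0.3)
        scaled = els_objective(10 * y, 10 * f, 0.3)
        assert scaled - base == pytest.approx(2 * len(y) * math.log(10.0),
                                              rel=1e-10)

    def test_equals_minus_two_gaussian_loglik_up_to_constant(self):
        """O = -2 log L + n ln(2 pi) for Normal(f, (sigma f)^2)."""
        y = np.array([3.0, 8.0, 14.0])
        f = np.array([4.0, 7.0, 12.0])
        sigma = 0.35
        loglik = float(np.sum(norm.logpdf(y, loc=f, scale=sigma * f)))
        assert els_objective(y, f, sigma) == pytest.approx(
            -2 * loglik - len(y) * math.log(2 * math.pi), rel=1e-10)

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(ValueError):
            els_objective([1.0], [0.0], 0.5)


class TestFitAnimal:
    def test_noise_free_recovery_of_F(self, fit_init):
        design = StudyDesign(groups=[GroupDesign("g", 1, true_F=9.6)],
                             noise_cv_plasma=0.0, noise_cv_pbmc=0.0,
                             true_vmkm=1.0, seed=5)
        sub, regimen, _ = _one_animal(design)
        fit = fit_animal(sub, regimen, fit_init, free=("F",))
        assert fit.param("F") == pytest.approx(9.6, rel=1e-3)

    def test_noise_free_recovery_of_F_and_vmkm_full_ode_path(self, fit_init):
        design = StudyDesign(groups=[GroupDesign("g", 1, true_F=9.6)],
                             noise_cv_plasma=0.0, noise_cv_pbmc=0.0,
                             true_vmkm=2.0, seed=6)
        sub, regimen, _ = _one_animal(design)
        fit = fit_animal(sub, regimen, fit_init, free=("F", "vmkm"),
                         fast=False)
        assert fit.param("F") == pytest.approx(9.6, rel=1e-3)
        assert fit.param("vmkm") == pytest.approx(2.0, rel=1e-3)

    def test_fast_and_full_paths_agree(self, fit_init):
        design = StudyDesign(groups=[GroupDesign("g", 1, true_F=9.6)], seed=7)
        sub, regimen, _ = _one_animal(design)
        fast = fit_animal(sub, regimen, fit_init, free=("F", "vmkm"),
                          fast=True)
        full = fit_animal(sub, regimen, fit_init, free=("F", "vmkm"),
                          fast=False)
        # folding the formation loss at its reference value perturbs the
        # optimum by ~vmkm/Cl, a few percent at most
        assert fast.param("F") == pytest.approx(full.param("F"), rel=0.05)
        assert fast.param("vmkm") == pytest.approx(full.param("vmkm"),
                                                   rel=0.05)

    def test_optimum_beats_log_grid(self, fit_init):
        """The returned optimum is at least as good as a 20x20 log-grid of
        (F, vmkm) around it, scored by an independently coded profiled ELS."""
        design = StudyDesign(groups=[GroupDesign("g", 1, true_F=9.6)], seed=8)
        sub, regimen, _ = _one_animal(design)
        fit = fit_animal(sub, regimen, fit_init, free=("F", "vmkm"),
                         fast=False)
        obs = sub[~sub["is_bloq"]].sort_values(["matrix", "time_d"])
        y = obs["value"].to_numpy()
        mats = obs["matrix"].to_numpy()

        def profiled_els(params):
            f = predict_observations(params, regimen, obs)
            total = float(np.sum(np.log(f**2)))
            for m in np.unique(mats):
                r2 = ((y[mats == m] - f[mats == m]) / f[mats == m]) ** 2
                total += len(r2) * (1.0 + math.log(max(r2.mean(), 1e-12)))
            return total

        best = profiled_els(fit.estimates)
        assert best == pytest.approx(fit.objective, rel=1e-6)
        for lf in np.linspace(-0.4, 0.4, 20):
            for lv in np.linspace(-0.4, 0.4, 20):
                trial = fit.estimates.with_updates(
                    F=fit.param("F") * math.exp(lf),
                    vmkm=fit.param("vmkm") * math.exp(lv))
                assert profiled_els(trial) >= best - 1e-6 * abs(best)

    def test_estimates_invariant_to_record_order(self, fit_init):
        design = StudyDesign(groups=[GroupDesign("g", 1, true_F=5.0)], seed=9)
        sub, regimen, _ = _one_animal(design)
        shuffled = sub.sample(frac=1.0, random_state=42)
        a = fit_animal(sub, regimen, fit_init)
        b = fit_animal(shuffled, regimen, fit_init)
        assert a.param("F") == pytest.approx(b.param("F"), rel=1e-9)
        assert a.param("vmkm") == pytest.approx(b.param("vmkm"), rel=1e-9)

    def test_monte_carlo_recovery_at_study_noise_levels(self, fit_init):
        """Median relative bias of F and vmkm stays under 10% across virtual
        dogs sampled on the implant-study schedule with ~75%/105% CV noise."""
        bias_f, bias_v = [], []
        for seed in range(30):
            design = StudyDesign(groups=[GroupDesign("g", 1, true_F=9.6)],
                                 true_vmkm=2.0, seed=seed)
            sub, regimen, _ = _one_animal(design)
            fit = fit_animal(sub, regimen, fit_init)
            bias_f.append(fit.param("F") / 9.6 - 1.0)
            bias_v.append(fit.param("vmkm") / 2.0 - 1.0)
        assert abs(np.median(bias_f)) < 0.10
        assert abs(np.median(bias_v)) < 0.10

    def test_lower_noise_gives_tighter_estimates(self, fit_init):
        """Monotone precision: 10x less noise shrinks the estimator spread."""
        spreads = []
        for cv_scale in (1.0, 0.1):
            ests = []
            for seed in range(12):
                design = StudyDesign(
                    groups=[GroupDesign("g", 1, true_F=9.6)],
                    noise_cv_plasma=0.746 * cv_scale,
                    noise_cv_pbmc=1.05 * cv_scale, seed=seed)
                sub, regimen, _ = _one_animal(design)
                ests.append(fit_animal(sub, regimen, fit_init).param("F"))
            spreads.append(np.std(np.log(ests)))
        assert spreads[1] < spreads[0]

    def test_too_few_observations_rejected(self, fit_init, implant_regimen):
        obs = pd.DataFrame({
            "animal": ["a"], "group": ["g"], "matrix": ["plasma_tfv"],
            "time_d": [10.0], "value": [25.0], "lloq": [1.0],
            "is_bloq": [False]})
        with pytest.raises(ValueError):
            fit_animal(obs, implant_regimen, fit_init, free=("F", "vmkm"))


class TestSummarizeGroup:
    @staticmethod
    def _fits(values):
        results = []
        for v in values:
            p = PKParameters(F=v)
            results.append(type("R", (), {
                "free": ("F",), "param": lambda self, n, _v=v: _v})())
        return results

    def test_hand_computed_summary(self):
        vals = [8.90, 9.82, 16.3, 9.82]
        df = summarize_group(self._fits(vals))
        mean = sum(vals) / 4
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 3)
        assert df.loc["F", "mean"] == pytest.approx(mean)
        assert df.loc["F", "cv_percent"] == pytest.approx(100 * sd / mean)
        assert df.loc["F", "median"] == pytest.approx((9.82 + 9.82) / 2)
        assert df.loc["F", "min"] == 8.90
        assert df.loc["F", "max"] == 16.3

    def test_single_fit_has_no_cv(self):
        df = summarize_group(self._fits([4.2]))
        assert math.isnan(df.loc["F", "cv_percent"])

    def test_identical_fits_have_zero_cv(self):
        df = summarize_group(self._fits([3.3, 3.3, 3.3]))
        assert df.loc["F", "cv_percent"] == pytest.approx(0.0, abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([])


class TestComodel:
    @staticmethod
    def _studies(seed_iv=11, seed_imp=12, noise=0.05):
        iv = StudyDesign(study="iv", kind="iv",
                         groups=[GroupDesign("IV", 2, n_implants=0,
                                             true_F=1.0)],
                         noise_cv_plasma=noise, noise_cv_pbmc=noise,
                         true_vmkm=2.0, seed=seed_iv)
        imp = StudyDesign(study="imp",
                          groups=[GroupDesign("single", 2, true_F=9.6)],
                          noise_cv_plasma=noise, noise_cv_pbmc=noise,
                          true_vmkm=2.0, seed=seed_imp)
        return generate_study(iv), generate_study(imp)

    def test_shared_parameter_and_group_F_recovered(self, fit_init):
        """IV anchor + implant study generated from one truth: the shared
        clearance and the implant-group F come back near their true values."""
        siv, simp = self._studies()
        res = comodel([siv.observation_set(), simp.observation_set()],
                      fit_init.with_updates(Cl=140.0), shared=("Cl",),
                      max_outer=4, tol=1e-4)
        assert res.shared.Cl == pytest.approx(174.0, rel=0.03)
        assert res.group_summaries["single"].loc["F", "mean"] == \
            pytest.approx(9.6, rel=0.10)

    def test_requires_iv_anchor_for_systemic_parameters(self, fit_init):
        _, simp = self._studies()
        with pytest.raises(ValueError, match="IV"):
            comodel([simp.observation_set()], fit_init, shared=("Cl",))

    def test_replication_invariance(self, fit_init):
        """Fitting the same study twice gives identical estimates."""
        _, simp = self._studies()
        r1 = comodel([simp.observation_set()], fit_init, shared=())
        r2 = comodel([simp.observation_set()], fit_init, shared=())
        for a in r1.animal_fits:
            assert r1.animal_fits[a].param("F") == r2.animal_fits[a].param("F")

    def test_recovers_bioavailability_ordering(self, fit_init):
        """Groups generated with F_single=9.6 > F_dual=1.5 keep that
        ordering in the fitted group means."""
        design = StudyDesign(groups=[
            GroupDesign("single", 3, true_F=9.6),
            GroupDesign("dual-one-pocket", 3, n_implants=2, true_F=1.5),
        ], true_vmkm=2.0, seed=21)
        study = generate_study(design)
        res = comodel([study.observation_set()], fit_init, shared=())
        f_single = res.group_summaries["single"].loc["F", "mean"]
        f_dual = res.group_summaries["dual-one-pocket"].loc["F", "mean"]
        assert f_single > f_dual


def test_observation_set_validation(implant_regimen):
    data = pd.DataFrame({
        "animal": ["a"], "group": ["g"], "matrix": ["plasma_tfv"],
        "time_d": [1.0], "value": [5.0], "lloq": [1.0], "is_bloq": [False]})
    ObservationSet(data=data, regimens={"a": implant_regimen})
    with pytest.raises(ValueError, match="regimen"):
        ObservationSet(data=data, regimens={})
    bad = data.assign(value=[-1.0])
    with pytest.raises(ValueError, match="positive"):
        ObservationSet(data=bad, regimens={"a": implant_regimen})
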