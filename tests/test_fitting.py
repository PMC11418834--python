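"""Ensemble averaging and the single-state von Mises fit."""

import warnings

import numpy as np
import pytest

from maat import (
    CouplingMeasurement,
    MaatFitter,
    VonMisesModel,
    evaluate,
    expected_j,
    fit_group,
    fit_single_state,
    make_pseudo_experiment,
    reference_equation_set,
    rmsd_profile,
)
from maat.fitting import coupling_kind


class TestExpectedJ:
    def test_point_mass_limit(self, ref_equations):
        model = VonMisesModel(37.0, 0.6)  # at the kappa ceiling
        for eq in ref_equations:
            assert expected_j(eq, model) == pytest.approx(
                evaluate(eq, 37.0), abs=0.02
            )

    def test_uniform_limit_gives_mean_coefficient(self, ref_equations):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = VonMisesModel(123.0, 1e7)
        for eq in ref_equations:
            assert expected_j(eq, model) == eq.a[0]

    def test_bessel_quadrature_sampling_agree(self, ref_equations, rng):
        model = VonMisesModel(37.0, 15.0)
        for eq in ref_equations:
            closed = expected_j(eq, model)
            quad = expected_j(eq, model, method="quadrature")
            assert closed == pytest.approx(quad, abs=1e-6)
            draws = model.rvs(200_000, rng)
            vals = evaluate(eq, draws)
            mc_se = vals.std() / np.sqrt(vals.size)
            assert closed == pytest.approx(vals.mean(), abs=3 * mc_se)


class TestCouplingKind:
    @pytest.mark.parametrize(
        "cid,kind",
        [
            ("2JC1C4", "2JCOC"),
            ("2JC2H1", "2JCCH"),
            ("3JC2C4", "3JCOCC"),
            ("3JH1C4", "3JCOCH"),
            ("2JCCH", "2JCCH"),
        ],
    )
    def test_classification(self, cid, kind):
        assert coupling_kind(cid) == kind

    def test_unknown_rejected(self):
        with pytest.raises(ValueError):
            coupling_kind("JHH")


class TestSingleStateFit:
    def test_noise_free_self_consistency(self, ref_equations, truth_model):
        meas = make_pseudo_experiment(truth_model, ref_equations, 0.0, seed=0)
        res = fit_single_state(meas, ref_equations)
        assert res.mu == pytest.approx(truth_model.mu, abs=0.01)
        assert res.csd == pytest.approx(truth_model.csd, abs=0.01)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        assert res.converged

    def test_rmsd_is_root_mean_square_of_residuals(
        self, ref_equations, truth_model
    ):
        meas = make_pseudo_experiment(truth_model, ref_equations, 0.1, seed=3)
        res = fit_single_state(meas, ref_equations)
        r = np.array(list(res.residuals.values()))
        assert res.rmsd == pytest.approx(np.sqrt(np.mean(r**2)), abs=1e-8)

    def test_permutation_and_seed_invariance(self, ref_equations, truth_model):
        meas = make_pseudo_experiment(truth_model, ref_equations, 0.1, seed=5)
        a = fit_single_state(meas, ref_equations)
        b = fit_single_state(list(reversed(meas)), ref_equations)
        c = fit_single_state(meas, ref_equations, seed=987, n_starts=100)
        assert a.mu == pytest.approx(b.mu, abs=1e-6)
        assert a.mu == pytest.approx(c.mu, abs=1e-6)
        assert a.csd == pytest.approx(c.csd, abs=1e-6)

    def test_matches_pure_monte_carlo_search(self, ref_equations, truth_model):
        meas = make_pseudo_experiment(truth_model, ref_equations, 0.1, seed=2)
        refined = fit_single_state(meas, ref_equations)
        mc = fit_single_state(
            meas, ref_equations, method="mc", n_starts=20_000
        )
        assert mc.mu == pytest.approx(refined.mu, abs=2.0)
        assert mc.rmsd >= refined.rmsd - 1e-9

    def test_sign_flip_recovers_assumed_sign(self, ref_equations, truth_model):
        meas = make_pseudo_experiment(truth_model, ref_equations, 0.0, seed=0)
        flipped = [
            CouplingMeasurement(
                m.coupling_id,
                -m.value if m.coupling_id == "2JCCH" else m.value,
                sign_assumed=(m.coupling_id == "2JCCH"),
            )
            for m in meas
        ]
        res = fit_single_state(flipped, ref_equations)
        assert res.sign_flipped == ("2JCCH",)
        assert res.mu == pytest.approx(truth_model.mu, abs=0.1)

    def test_too_few_measurements(self, ref_equations):
        with pytest.raises(ValueError):
            fit_single_state(
                [CouplingMeasurement("2JCCH", 1.0)], ref_equations[:1]
            )

    def test_noisy_recovery(self, ref_equations, truth_model):
        mu_err, csd_err = [], []
        for rep in range(20):
            meas = make_pseudo_experiment(
                truth_model, ref_equations, 0.1, seed=rep
            )
            res = fit_single_state(meas, ref_equations)
            mu_err.append(abs(res.mu - truth_model.mu))
            csd_err.append(abs(res.csd - truth_model.csd))
        assert np.median(mu_err) < 2.0
        assert np.median(csd_err) < 3.0

    def test_csd_inflates_under_equation_error(self, truth_model):
        # CSDs are upper limits: systematic error in the parameterized
        # equations broadens the fitted distribution, never sharpens it
        ref = reference_equation_set(seed=0)
        ests = []
        for rep in range(15):
            gen = reference_equation_set(seed=100 + rep)
            meas = make_pseudo_experiment(truth_model, gen, 0.1, seed=rep)
            ests.append(
                fit_single_state(meas, ref, mu_bounds=(-60, 120)).csd
            )
        assert np.mean(ests) >= truth_model.csd


class TestFitGroup:
    def _measurements(self, ref_equations, truth_model):
        return make_pseudo_experiment(truth_model, ref_equations, 0.0, seed=1)

    def test_group_one_excludes_geminal_cch(self, ref_equations, truth_model):
        meas = self._measurements(ref_equations, truth_model)
        res = fit_group(meas, "I", ref_equations)
        assert len(res.residuals) == 3
        assert "2JCCH" not in res.residuals
        assert res.group_label == "I"

    def test_group_three_uses_all_four(self, ref_equations, truth_model):
        meas = self._measurements(ref_equations, truth_model)
        res = fit_group(meas, "III", ref_equations)
        assert sorted(res.residuals) == [
            "2JCCH", "2JCOC", "3JCOCC", "3JCOCH",
        ]

    def test_missing_coupling_named(self, ref_equations, truth_model):
        meas = [
            m
            for m in self._measurements(ref_equations, truth_model)
            if m.coupling_id != "2JCOC"
        ]
        with pytest.raises(ValueError, match="2JCOC"):
            fit_group(meas, "I", ref_equations)


class TestRmsdProfile:
    def test_minimum_matches_optimizer(self, ref_equations, truth_model):
        meas = make_pseudo_experiment(truth_model, ref_equations, 0.1, seed=9)
        res = fit_single_state(meas, ref_equations)
        prof = rmsd_profile(meas, ref_equations)
        mu_g, csd_g = prof.argmin
        assert abs(mu_g - res.mu) <= 0.5
        assert abs(csd_g - res.csd) <= 0.5
        assert prof.min_rmsd >= res.rmsd - 1e-9

    def test_single_coupling_underdetermined(self, ref_by_kind):
        meas = [CouplingMeasurement("3JCOCH", 4.0)]
        prof = rmsd_profile(
            meas, [ref_by_kind["3JCOCH"]], mu_step=2.0, csd_step=1.0
        )
        # one constraint, two parameters: a continuum of exact solutions
        lo, hi, width = prof.flat_csd_interval(0.01)
        assert width > 60.0

    def test_added_coupling_never_widens_flat_interval(
        self, ref_by_kind, truth_model
    ):
        three = [
            ref_by_kind[k] for k in ("2JCOC", "3JCOCC", "3JCOCH")
        ]
        four = three + [ref_by_kind["2JCCH"]]
        m4 = make_pseudo_experiment(truth_model, four, 0.0, seed=11)
        m3 = [m for m in m4 if m.coupling_id != "2JCCH"]
        w3 = rmsd_profile(m3, three, mu_step=2.0, csd_step=1.0)
        w4 = rmsd_profile(m4, four, mu_step=2.0, csd_step=1.0)
        assert (
            w4.flat_csd_interval(0.1)[2] <= w3.flat_csd_interval(0.1)[2]
        )


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        fitter = MaatFitter(n_starts=50, seed=7)
        params = fitter.get_params()
        assert params["n_starts"] == 50
        clone = MaatFitter(**params)
        assert clone.get_params() == params

    def test_predict_returns_expected_couplings(
        self, ref_equations, truth_model
    ):
        meas = make_pseudo_experiment(truth_model, ref_equations, 0.0, seed=0)
        fitter = MaatFitter().fit(ref_equations, [m.value for m in meas])
        np.testing.assert_allclose(
            fitter.predict(ref_equations),
            [m.value for m in meas],
            atol=1e-6,
        )
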