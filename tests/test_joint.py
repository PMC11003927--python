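"""Joint correlated-molar likelihood: oracles, factorization, MLE recovery."""

import math

import numpy as np
import pytest

from molarage import (
    Cohort,
    CorrelationSet,
    IdentifiabilityError,
    JointParameters,
    MolarClass,
    MolarCombinationModel,
    NotPositiveDefiniteError,
    Participant,
    Sex,
    SexStructure,
    SyntheticSpec,
    ToothRecord,
    VarianceWeight,
    fit_joint,
    fit_per_tooth,
    joint_loglik,
    load_parameters,
    mean_and_covariance,
    packaged_synthetic_parameters,
    simulate_cohort,
    write_parameters,
)

from conftest import make_fit, make_joint, volumes_for_y

F, S, T = MolarClass.FIRST, MolarClass.SECOND, MolarClass.THIRD


def bivariate_normal_logpdf(y1, y2, m1, m2, s1, s2, rho):
    """Independent closed-form oracle for the bivariate normal log-density."""
    z1, z2 = (y1 - m1) / s1, (y2 - m2) / s2
    q = (z1**2 - 2 * rho * z1 * z2 + z2**2) / (1 - rho**2)
    return (
        -math.log(2 * math.pi * s1 * s2 * math.sqrt(1 - rho**2)) - 0.5 * q
    )


def two_tooth_cohort(rows):
    """rows: (pid, sex, age, {class: y}) with classes mapped to 46/47/18."""
    teeth = {F: 46, S: 47, T: 18}
    participants, records = [], []
    for pid, sex, age, y_by_class in rows:
        participants.append(Participant(pid, sex, age))
        for cls, y in y_by_class.items():
            records.append(ToothRecord(pid, teeth[cls], *volumes_for_y(y)))
    return Cohort(participants, records)


class TestCorrelationSet:
    def test_boundary_rho_rejected(self):
        with pytest.raises(ValueError):
            CorrelationSet(rho_12=1.0)

    def test_non_positive_definite_triple_detected(self):
        bad = CorrelationSet(0.99, -0.99, 0.99)
        # oracle: smallest eigenvalue of the full 3x3 matrix is negative
        assert np.linalg.eigvalsh(bad.matrix()).min() < 0
        assert not bad.is_positive_definite()
        with pytest.raises(NotPositiveDefiniteError):
            bad.validate_positive_definite()

    def test_valid_triple_accepted(self):
        ok = CorrelationSet(0.620, 0.430, 0.598)
        assert ok.is_positive_definite()
        assert np.linalg.eigvalsh(ok.matrix()).min() > 0


class TestMeanAndCovariance:
    def test_zero_correlations_give_diagonal(self):
        params = make_joint({F: make_fit(46), S: make_fit(47), T: make_fit(18)})
        _, cov = mean_and_covariance(params, 18.0, Sex.F)
        assert np.allclose(cov, np.diag(np.diag(cov)))
        assert np.allclose(np.diag(cov), 0.2**2)

    def test_off_diagonal_product_rule(self):
        params = make_joint(
            {F: make_fit(46, sigma=0.1), S: make_fit(47, sigma=0.2)}, rho_12=0.5
        )
        _, cov = mean_and_covariance(params, 20.0, Sex.M)
        assert cov[0, 1] == pytest.approx(0.5 * 0.1 * 0.2)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_age_dependent_weights_enter_covariance(self):
        params = make_joint(
            {F: make_fit(46, weight=VarianceWeight.INV_AGE, sigma=0.05),
             S: make_fit(47, sigma=0.2)},
            rho_12=0.5,
        )
        _, cov = mean_and_covariance(params, 16.0, Sex.F)
        sd1 = 0.05 * math.sqrt(16.0)
        assert cov[0, 0] == pytest.approx(sd1**2)
        assert cov[0, 1] == pytest.approx(0.5 * sd1 * 0.2)

    def test_absent_class_rejected(self):
        params = make_joint({F: make_fit(46)})
        with pytest.raises(ValueError, match="not in model"):
            mean_and_covariance(params, 18.0, Sex.F, classes=[F, T])


class TestJointLoglik:
    def test_zero_correlation_factorises(self):
        spec = SyntheticSpec(seed=5)
        cohort = simulate_cohort(spec)
        truth = spec.true_model
        indep = make_joint(dict(truth.fits))
        total = joint_loglik(indep, cohort)
        from molarage.per_tooth import gaussian_loglik

        by_tooth = 0.0
        for cls, tooth in truth.tooth_by_class.items():
            fit = truth.fits[cls]
            for r in cohort.records_for(tooth=tooth):
                p = cohort.participant(r.participant_id)
                mu = fit.mean(p.age, p.sex)
                var = fit.variance(p.age)
                by_tooth += gaussian_loglik([r.y], mu, var, 1.0)
        assert total == pytest.approx(by_tooth, abs=1e-10 * max(1, abs(by_tooth)))

    def test_matches_bivariate_oracle(self):
        fits = {F: make_fit(46, sigma=0.11, beta0=-1.2, beta1=-0.07),
                S: make_fit(47, sigma=0.21, beta0=-1.4, beta1=-0.05)}
        params = make_joint(fits, rho_12=0.45)
        rows = [("P1", Sex.F, 17.3, {F: -2.5, S: -2.3}),
                ("P2", Sex.M, 21.1, {F: -2.9, S: -2.6})]
        cohort = two_tooth_cohort(rows)
        expected = 0.0
        for _, sex, age, ys in rows:
            expected += bivariate_normal_logpdf(
                ys[F], ys[S],
                fits[F].mean(age, sex), fits[S].mean(age, sex),
                math.sqrt(fits[F].variance(age)), math.sqrt(fits[S].variance(age)),
                0.45,
            )
        assert joint_loglik(params, cohort) == pytest.approx(expected, abs=1e-10)

    def test_partial_observation_contributes_marginal(self):
        fits = {F: make_fit(46), S: make_fit(47), T: make_fit(18, sigma=0.16)}
        params = make_joint(fits, rho_12=0.6, rho_13=0.4, rho_23=0.6)
        cohort = two_tooth_cohort([("P1", Sex.M, 19.0, {T: -2.2})])
        fit = fits[T]
        var = fit.variance(19.0)
        expected = -0.5 * math.log(2 * math.pi * var) - (
            (-2.2 - fit.mean(19.0, Sex.M)) ** 2 / (2 * var)
        )
        assert joint_loglik(params, cohort) == pytest.approx(expected, abs=1e-12)

    def test_non_positive_definite_gives_minus_inf(self):
        fits = {F: make_fit(46), S: make_fit(47), T: make_fit(18)}
        params = make_joint(fits, rho_12=0.99, rho_13=-0.99, rho_23=0.99)
        cohort = two_tooth_cohort([("P1", Sex.F, 18.0, {F: -2.5, S: -2.4, T: -2.1})])
        assert joint_loglik(params, cohort) == -math.inf

    def test_permutation_invariance(self):
        spec = SyntheticSpec(seed=9, n_female=30, n_male=20)
        cohort = simulate_cohort(spec)
        params = spec.true_model
        ll = joint_loglik(params, cohort)
        reordered = Cohort(list(reversed(cohort.participants)),
                           list(reversed(cohort.records)))
        assert joint_loglik(params, reordered) == pytest.approx(ll, abs=1e-8)


class TestFitJoint:
    def test_single_class_equals_per_tooth_fit(self):
        spec = SyntheticSpec(seed=21)
        cohort = simulate_cohort(spec)
        cfg = spec.true_model.fits[F].config
        res = fit_joint(cohort, {F: 46}, {46: cfg})
        direct = fit_per_tooth(cohort, cfg)
        assert res.params.fits[F].beta0 == pytest.approx(direct.beta0, abs=1e-6)
        assert res.params.fits[F].beta1 == pytest.approx(direct.beta1, abs=1e-6)
        assert res.params.fits[F].sigma == pytest.approx(direct.sigma, rel=1e-6)

    def test_optimum_improves_on_independence_start(self):
        spec = SyntheticSpec(seed=33, n_female=60, n_male=40)
        cohort = simulate_cohort(spec)
        truth = spec.true_model
        configs = {f.config.tooth: f.config for f in truth.fits.values()}
        res = fit_joint(cohort, truth.tooth_by_class, configs)
        indep_fits = {c: fit_per_tooth(cohort, configs[t])
                      for c, t in truth.tooth_by_class.items()}
        indep = make_joint(indep_fits)
        assert res.loglik >= joint_loglik(indep, cohort) - 1e-8

    def test_correlation_recovery_moderate_n(self):
        truth = packaged_synthetic_parameters()
        spec = SyntheticSpec(
            true_model=truth, n_female=300, n_male=300,
            missingness={c: 0.0 for c in (F, S, T)}, seed=77,
        )
        cohort = simulate_cohort(spec)
        configs = {f.config.tooth: f.config for f in truth.fits.values()}
        res = fit_joint(cohort, truth.tooth_by_class, configs)
        r = res.params.correlations
        assert r.rho_12 == pytest.approx(0.620, abs=0.10)
        assert r.rho_13 == pytest.approx(0.430, abs=0.12)
        assert r.rho_23 == pytest.approx(0.598, abs=0.10)

    def test_profile_loglik_locally_concave_at_mle(self):
        spec = SyntheticSpec(seed=13, n_female=60, n_male=40,
                             missingness={c: 0.0 for c in (F, S, T)})
        cohort = simulate_cohort(spec)
        truth = spec.true_model
        configs = {f.config.tooth: f.config for f in truth.fits.values()}
        res = fit_joint(cohort, truth.tooth_by_class, configs)
        p = res.params
        eps = 0.02
        for attr in ("rho_12", "rho_13", "rho_23"):
            def ll(delta):
                kwargs = {a: getattr(p.correlations, a) for a in
                          ("rho_12", "rho_13", "rho_23")}
                kwargs[attr] += delta
                shifted = JointParameters(
                    dict(p.tooth_by_class), dict(p.fits), CorrelationSet(**kwargs)
                )
                return joint_loglik(shifted, cohort)
            second_diff = ll(eps) - 2 * ll(0.0) + ll(-eps)
            assert second_diff < 0

    def test_two_stage_close_to_joint(self):
        spec = SyntheticSpec(seed=55, n_female=120, n_male=80,
                             missingness={c: 0.0 for c in (F, S, T)})
        cohort = simulate_cohort(spec)
        truth = spec.true_model
        configs = {f.config.tooth: f.config for f in truth.fits.values()}
        joint = fit_joint(cohort, truth.tooth_by_class, configs, method="joint")
        two = fit_joint(cohort, truth.tooth_by_class, configs, method="two_stage")
        for attr in ("rho_12", "rho_13", "rho_23"):
            assert getattr(two.params.correlations, attr) == pytest.approx(
                getattr(joint.params.correlations, attr), abs=0.08
            )
        assert joint.loglik >= two.loglik - 1e-6

    def test_no_shared_teeth_unidentifiable(self):
        rows = [("P1", Sex.F, 17.0, {F: -2.5}), ("P2", Sex.M, 19.0, {S: -2.4}),
                ("P3", Sex.F, 21.0, {T: -2.2}), ("P4", Sex.M, 16.0, {F: -2.3})]
        cohort = two_tooth_cohort(rows)
        cfgs = {46: make_fit(46).config, 47: make_fit(47).config,
                18: make_fit(18).config}
        with pytest.raises(IdentifiabilityError, match="two or more"):
            MolarCombinationModel(cohort, {F: 46, S: 47, T: 18}, cfgs)


class TestParameterFiles:
    def test_packaged_fixture_is_valid(self):
        params = packaged_synthetic_parameters()
        assert params.label == "46-47-18"
        assert params.correlations.rho_12 == pytest.approx(0.620)
        assert params.fits[F].config.sex_structure is SexStructure.FULL_INTERACTION
        assert params.loglik is None

    def test_round_trip_identity(self, tmp_path):
        params = packaged_synthetic_parameters()
        path = tmp_path / "params.yaml"
        write_parameters(params, path)
        back = load_parameters(path)
        assert back.tooth_by_class == params.tooth_by_class
        assert back.correlations == params.correlations
        for c in params.classes:
            a, b = params.fits[c], back.fits[c]
            assert (a.beta0, a.beta1, a.beta2, a.beta3, a.sigma) == (
                b.beta0, b.beta1, b.beta2, b.beta3, b.sigma)
            assert a.config == b.config

    def test_invalid_correlation_triple_rejected(self, tmp_path):
        params = packaged_synthetic_parameters()
        path = tmp_path / "bad.yaml"
        write_parameters(params, path)
        text = path.read_text().replace(
            "rho_12: 0.62", "rho_12: 0.99").replace(
            "rho_13: 0.43", "rho_13: -0.99").replace(
            "rho_23: 0.598", "rho_23: 0.99")
        path.write_text(text)
        with pytest.raises(NotPositiveDefiniteError):
            load_parameters(path)

    def test_missing_parameter_rejected(self, tmp_path):
        params = packaged_synthetic_parameters()
        path = tmp_path / "missing.yaml"
        write_parameters(params, path)
        path.write_text(path.read_text().replace("correlations:", "korrelations:"))
        with pytest.raises(ValueError, match="missing"):
            load_parameters(path)
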