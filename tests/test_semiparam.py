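import numpy as np
import pandas as pd
import pytest

import altrec
from altrec import ConvergenceError, parse_long_table
from altrec.nonparam import DataInvariantError
from altrec.semiparam import (
    RegressionSpec,
    censoring_km,
    chang_U,
    chang_transform,
    coef,
    confint,
    default_L,
    lee_D,
    lee_vcov,
    o_kernel,
    parzen_resample_vcov,
    solve_chang,
    solve_lee,
    summarize,
    vcov,
)
from conftest import random_table, t1_frame
from _oracles import chang_U_oracle, lee_D_oracle


def _sim(nsize=150, seed=0, **kw):
    return altrec.sim_bivariate_recurrent(
        altrec.SimulationScenario(nsize=nsize, seed=seed, **kw)
    )


class TestChangTransform:
    def test_identity_at_zero(self, t1_cov):
        A = np.array([[1.0], [0.0], [0.0]])
        Xt, Zt, dXt, dZt = chang_transform(t1_cov, A, np.zeros(2))
        assert np.allclose(Xt, t1_cov.df["xij"])
        assert np.allclose(Zt, t1_cov.df["xij"] + t1_cov.df["yij"])
        assert np.array_equal(dXt, t1_cov.df["d1"])
        assert np.array_equal(dZt, t1_cov.df["d2"])

    def test_single_subject_arithmetic(self):
        # A = 1, b1 = log 2, b2 = 0, (X, Y) = (4, 2): X~0 = 2, Z~0 = 4
        df = pd.DataFrame(
            [(1, 1, 4.0, 2.0, 1, 1), (1, 2, 10.0, 4.0, 1, 0)],
            columns=["id", "episode", "xij", "yij", "d1", "d2"],
        )
        df["a"] = 1.0
        table = parse_long_table(df, covariate_names=["a"])
        A = np.array([[1.0]])
        Xt, Zt, _, _ = chang_transform(table, A, np.array([np.log(2), 0.0]))
        assert Xt[0] == pytest.approx(2.0)
        assert Zt[0] == pytest.approx(4.0)

    def test_matches_recursive_oracle(self, t1_cov):
        from _oracles import chang_transform_oracle

        A = t1_cov.covariate_matrix()
        b = np.array([0.5, -0.5])
        Xt, Zt, dXt, dZt = chang_transform(t1_cov, A, b)
        flat = [row for sub in chang_transform_oracle(t1_cov, A, b) for row in sub]
        assert np.allclose(Xt, [r[0] for r in flat], atol=1e-12)
        assert np.allclose(Zt, [r[1] for r in flat], atol=1e-12)
        assert np.array_equal(dXt, [r[2] for r in flat])
        assert np.array_equal(dZt, [r[3] for r in flat])


class TestChangU:
    def test_identical_covariates_give_zero(self):
        df = t1_frame()
        df["a"] = 1.0
        table = parse_long_table(df, covariate_names=["a"])
        A = table.covariate_matrix()
        for b in (np.zeros(2), np.array([0.3, -0.7])):
            U1, U2 = chang_U(table, A, b)
            assert np.allclose(U1, 0.0)
            assert np.allclose(U2, 0.0)

    def test_single_subject_gives_zero(self):
        df = pd.DataFrame(
            [(1, 1, 2.0, 3.0, 1, 1), (1, 2, 4.0, 2.0, 1, 0)],
            columns=["id", "episode", "xij", "yij", "d1", "d2"],
        )
        df["a"] = 1.0
        table = parse_long_table(df, covariate_names=["a"])
        U1, U2 = chang_U(table, table.covariate_matrix(), np.zeros(2))
        assert np.allclose(U1, 0.0)
        assert np.allclose(U2, 0.0)

    def test_matches_brute_force_oracle(self, t1_cov):
        A = t1_cov.covariate_matrix()
        for b in (np.zeros(2), np.array([0.4, -0.2]), np.array([-0.3, 0.6])):
            U1, U2 = chang_U(t1_cov, A, b)
            o1, o2 = chang_U_oracle(t1_cov, A, b)
            assert np.allclose(U1, o1, atol=1e-12)
            assert np.allclose(U2, o2, atol=1e-12)

    def test_oracle_on_random_tables_with_two_covariates(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            table = random_table(rng, n=int(rng.integers(3, 7)), p=2)
            A = table.covariate_matrix()
            b = rng.uniform(-0.5, 0.5, 4)
            U1, U2 = chang_U(table, A, b)
            o1, o2 = chang_U_oracle(table, A, b)
            assert np.allclose(U1, o1, atol=1e-12)
            assert np.allclose(U2, o2, atol=1e-12)


class TestSolveChang:
    def test_constant_covariate_is_nonconvergence(self):
        df = t1_frame()
        df["a"] = 1.0
        table = parse_long_table(df, covariate_names=["a"])
        with pytest.raises(ConvergenceError) as exc:
            solve_chang(RegressionSpec(table, ["a"], method="chang"))
        assert str(exc.value).startswith(
            "Error: Max Iterations reached. Did not converge."
        )

    def test_zero_iteration_cap_is_nonconvergence(self):
        table = _sim(nsize=40, seed=2)
        with pytest.raises(ConvergenceError):
            solve_chang(RegressionSpec(table, ["a1"], method="chang", max_iter=0))

    def test_null_data_estimates_near_zero(self):
        table = _sim(nsize=150, seed=9, beta1=(0, 0), beta2=(0, 0))
        fit = solve_chang(RegressionSpec(table, ["a1", "a2"], method="chang", seed=1))
        # 3 Monte-Carlo SDs of the estimator at this design
        assert np.all(np.abs(fit.beta1) < 0.45)
        assert np.all(np.abs(fit.beta2) < 0.45)


class TestParzenResampling:
    def test_single_replicate_rejected(self):
        table = _sim(nsize=40, seed=4)
        spec = RegressionSpec(table, ["a1"], method="chang", n_resample=1, seed=0)
        fit = solve_chang(spec)
        with pytest.raises(ValueError):
            parzen_resample_vcov(spec, fit)

    def test_deterministic_given_seed(self):
        table = _sim(nsize=40, seed=4)
        spec = RegressionSpec(table, ["a1"], method="chang", n_resample=12, seed=7)
        fit = solve_chang(spec)
        v1 = parzen_resample_vcov(spec, fit).copy()
        v2 = parzen_resample_vcov(spec, fit)
        assert np.array_equal(v1, v2)
        assert np.all(np.linalg.eigvalsh(v1) > -1e-10)


class TestCensoringKM:
    def test_no_censoring_events_gives_unit_survival(self):
        rows = []
        for i in range(3):
            rows += [(i, 1, 2.0 + i, 3.0, 1, 1), (i, 2, 4.0, 2.0, 1, 0)]
        table = parse_long_table(
            pd.DataFrame(rows, columns=["id", "episode", "xij", "yij", "d1", "d2"])
        )
        km = censoring_km(table, which=1)
        assert np.all(km.G([1.0, 5.0, 100.0]) == 1.0)

    def test_all_events_stepwise(self):
        # first-episode Type I times (2, 5, 7), all censoring events
        rows = [
            (1, 1, 2.0, 0.0, 0, 0),
            (2, 1, 5.0, 0.0, 0, 0),
            (3, 1, 7.0, 0.0, 0, 0),
            (4, 1, 1.0, 1.0, 1, 1),
            (4, 2, 1.0, 1.0, 1, 0),
        ]
        table = parse_long_table(
            pd.DataFrame(rows, columns=["id", "episode", "xij", "yij", "d1", "d2"])
        )
        km = censoring_km(table, which=1)
        # risk sets of size 5,... but only subjects 1-3 are events
        g2, g5, g7 = km.G([2.0, 5.0, 7.0])
        assert g2 > g5 > g7
        assert km.G([1.9])[0] == pytest.approx(1.0, abs=1e-12)

    def test_toy_drop_only_at_censoring_time(self, t1):
        km = censoring_km(t1, which=1)
        # first-episode X times (2, 1, 5) with censoring indicators (0, 0, 1)
        assert km.G([2.0])[0] == 1.0
        assert km.G([4.9])[0] == 1.0
        assert km.G([5.0])[0] == pytest.approx(0.0)

    def test_three_event_no_ties_values(self):
        from lifelines import KaplanMeierFitter

        t = np.array([2.0, 5.0, 7.0])
        km = KaplanMeierFitter().fit(t, event_observed=[1, 1, 1])
        s = km.survival_function_.iloc[:, 0]
        assert np.allclose(s.loc[[2.0, 5.0, 7.0]], [2 / 3, 1 / 3, 0.0])


class TestOKernel:
    def test_diagonal_at_bound_is_zero(self):
        assert o_kernel(10.0, 10.0, 10.0) == 0.0

    def test_direct_substitution(self):
        assert o_kernel(1.0, 2.0, 10.0) == pytest.approx(np.log(2) - np.log(10))

    def test_symmetric_nonpositive_monotone(self):
        rng = np.random.default_rng(0)
        s, t = rng.uniform(0.1, 20, 50), rng.uniform(0.1, 20, 50)
        L = 12.0
        assert np.allclose(o_kernel(s, t, L), o_kernel(t, s, L))
        assert np.all(o_kernel(s, t, L) <= 0)
        tt = np.sort(t)
        assert np.all(np.diff(o_kernel(5.0, tt, L)) >= -1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            o_kernel(-1.0, 2.0, 10.0)


class TestLeeD:
    def test_identical_covariates_rejected(self):
        df = t1_frame()
        df["a"] = 1.0
        table = parse_long_table(df, covariate_names=["a"])
        with pytest.raises(DataInvariantError, match="no covariate variation"):
            lee_D(table, table.covariate_matrix(), np.zeros(2))

    def test_matches_quadruple_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(4):
            table = random_table(rng, n=int(rng.integers(2, 5)), p=1)
            A = table.covariate_matrix()
            km1 = censoring_km(table, 1)
            km2 = censoring_km(table, 2)
            L = 0.9 * default_L(table)
            for b in (np.zeros(2), rng.uniform(-0.5, 0.5, 2)):
                D1, D2 = lee_D(table, A, b, km1, km2, L)
                o1, o2 = lee_D_oracle(table, A, b, km1, km2, L)
                assert np.allclose(D1, o1, atol=1e-12)
                assert np.allclose(D2, o2, atol=1e-12)

    def test_oracle_with_two_covariates(self):
        rng = np.random.default_rng(13)
        table = random_table(rng, n=4, p=2)
        A = table.covariate_matrix()
        km1, km2 = censoring_km(table, 1), censoring_km(table, 2)
        L = 0.9 * default_L(table)
        b = np.array([0.2, -0.3, 0.1, 0.4])
        D1, D2 = lee_D(table, A, b, km1, km2, L)
        o1, o2 = lee_D_oracle(table, A, b, km1, km2, L)
        assert np.allclose(D1, o1, atol=1e-12)
        assert np.allclose(D2, o2, atol=1e-12)

    def test_componentwise_monotone_in_b1(self):
        table = _sim(nsize=30, seed=21)
        A = table.covariate_matrix()[:, :1]
        grid = np.linspace(-1, 1, 9)
        vals = [lee_D(table, A, np.array([b, 0.0]))[0][0] for b in grid]
        assert np.all(np.diff(vals) >= -1e-10)


class TestSolveLee:
    def test_deterministic(self):
        table = _sim(nsize=80, seed=31)
        f1 = solve_lee(RegressionSpec(table, ["a1", "a2"]))
        f2 = solve_lee(RegressionSpec(table, ["a1", "a2"]))
        assert np.array_equal(f1.beta, f2.beta)
        assert f1.converged and f1.residual_norm < 1e-8

    def test_null_recovery(self):
        table = _sim(nsize=150, seed=33, beta1=(0, 0), beta2=(0, 0))
        fit = solve_lee(RegressionSpec(table, ["a1", "a2"]))
        assert np.all(np.abs(fit.beta) < 0.45)

    def test_zero_iteration_cap_is_nonconvergence(self):
        table = _sim(nsize=40, seed=2)
        with pytest.raises(ConvergenceError) as exc:
            solve_lee(RegressionSpec(table, ["a1"], max_iter=0))
        assert "Error: Max Iterations reached. Did not converge." in str(exc.value)

    def test_location_invariance_and_scale_equivariance(self):
        table = _sim(nsize=100, seed=35)
        base = solve_lee(RegressionSpec(table, ["a1", "a2"]))
        shifted = table.df.copy()
        shifted["a2"] = shifted["a2"] + 5.0
        t_shift = parse_long_table(shifted, covariate_names=["a1", "a2"])
        f_shift = solve_lee(RegressionSpec(t_shift, ["a1", "a2"]))
        assert np.allclose(f_shift.beta, base.beta, atol=1e-6)
        scaled = table.df.copy()
        scaled["a2"] = scaled["a2"] * 4.0
        t_scale = parse_long_table(scaled, covariate_names=["a1", "a2"])
        f_scale = solve_lee(RegressionSpec(t_scale, ["a1", "a2"]))
        assert np.allclose(f_scale.beta[[1, 3]], base.beta[[1, 3]] / 4.0, atol=1e-6)
        assert np.allclose(f_scale.beta[[0, 2]], base.beta[[0, 2]], atol=1e-6)


class TestLeeVcov:
    def test_symmetric_psd_and_deterministic(self):
        table = _sim(nsize=80, seed=41)
        spec = RegressionSpec(table, ["a1", "a2"], seed=5)
        fit = solve_lee(spec)
        V1 = lee_vcov(spec, fit, n_boot=100).copy()
        V2 = lee_vcov(spec, fit, n_boot=100)
        assert np.array_equal(V1, V2)
        assert np.allclose(V1, V1.T)
        assert np.all(np.linalg.eigvalsh(V1) > -1e-12)

    def test_agrees_with_full_bootstrap(self):
        """Kernel-bootstrap sandwich SEs within 30% of refit-bootstrap SEs."""
        table = _sim(nsize=150, seed=43)
        spec = RegressionSpec(table, ["a1"], seed=5)
        fit = solve_lee(spec)
        se_sand = np.sqrt(np.diag(lee_vcov(spec, fit, n_boot=200)))
        se_full = np.sqrt(
            np.diag(lee_vcov(spec, fit, n_boot=60, full_bootstrap=True))
        )
        assert np.all(np.abs(se_sand / se_full - 1) < 0.30)


@pytest.fixture(scope="module")
def fitted():
    table = _sim(nsize=80, seed=51)
    spec = RegressionSpec(table, ["a1", "a2"], seed=3)
    fit = solve_lee(spec)
    lee_vcov(spec, fit, n_boot=100)
    return fit


class TestSummaries:
    def test_wald_arithmetic(self, fitted):
        # z and two-sided p from a known estimate/SE pair
        from scipy import stats

        z = 0.56 / 0.207
        assert z == pytest.approx(2.705, abs=0.01)
        assert 2 * stats.norm.sf(z) == pytest.approx(0.007, abs=0.001)
        tab = summarize(fitted)
        assert np.allclose(tab["z"], tab["estimate"] / tab["se"])
        assert np.allclose(
            tab["p_value"], 2 * stats.norm.sf(np.abs(tab["z"]))
        )

    def test_confint_default_level(self, fitted):
        ci = confint(fitted, level=0.95)
        assert np.allclose(
            ci["ci_low"], fitted.beta - 1.959964 * fitted.se, atol=1e-6
        )

    def test_confint_subsetting_and_unknown_name(self, fitted):
        one = confint(fitted, parm=["a1 (Type I)"])
        assert list(one.index) == ["a1 (Type I)"]
        with pytest.raises(KeyError, match="valid names"):
            confint(fitted, parm=["nope"])

    def test_vcov_frame_and_coef(self, fitted):
        V = vcov(fitted)
        assert list(V.index) == fitted.names
        assert np.allclose(V.values, V.values.T)
        assert coef(fitted).tolist() == fitted.beta.tolist()

    def test_unconverged_fit_refuses_summary(self, fitted):
        import copy

        broken = copy.copy(fitted)
        broken.converged = False
        with pytest.raises(ValueError, match="converge"):
            coef(broken)


def test_chang_location_invariance_of_type1_stage():
    """The Type I rank statistic depends on covariates only through
    risk-set centering and a common rescaling of the transformed times,
    so a location shift leaves beta1 unchanged.  (The Type II statistic
    mixes two scale factors, so its invariance is only approximate.)"""
    table = _sim(nsize=60, seed=61)
    shifted = table.df.copy()
    shifted["a2"] = shifted["a2"] + 3.0
    t_shift = parse_long_table(shifted, covariate_names=["a1", "a2"])
    c0 = solve_chang(RegressionSpec(table, ["a1", "a2"], method="chang", seed=1))
    c1 = solve_chang(RegressionSpec(t_shift, ["a1", "a2"], method="chang", seed=1))
    assert np.allclose(c0.beta1, c1.beta1, atol=5e-3)
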