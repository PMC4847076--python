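"""Generator checks: correlation structure, transforms, moments, determinism."""

import numpy as np
import pytest

from gelrct import (
    CASES,
    Scenario,
    TrialData,
    apply_treatment_transform,
    assign_groups,
    equicorrelation_matrix,
    sample_base,
    sample_part3,
    theoretical_group2_moments,
)
from gelrct.dgp import PART3_SD_Y

from conftest import SEED


class TestEquicorrelation:
    def test_identity_at_rho_zero(self):
        assert np.array_equal(equicorrelation_matrix(3, 0.0), np.eye(3))

    def test_eigenvalues(self):
        C = equicorrelation_matrix(3, 0.5)
        assert np.allclose(C[~np.eye(3, dtype=bool)], 0.5)
        ev = np.linalg.eigvalsh(C)
        # 1 - rho twice, 1 + 2 rho once
        assert np.allclose(np.sort(ev), [0.5, 0.5, 2.0])

    def test_bivariate(self):
        C = equicorrelation_matrix(2, 0.35)
        assert C[0, 1] == C[1, 0] == 0.35

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            equicorrelation_matrix(3, -0.6)


class TestAssignGroups:
    @pytest.mark.parametrize("n,delta,n_control", [(200, 0.5, 100),
                                                   (200, 0.2, 160)])
    def test_block_layout(self, n, delta, n_control):
        z = assign_groups(n, delta)
        assert (z[:n_control] == 0).all() and (z[n_control:] == 1).all()

    def test_non_integral_split_rejected(self):
        with pytest.raises(ValueError):
            assign_groups(10, 0.25)


class TestTreatmentTransform:
    def test_identity_when_null(self, rng):
        y0 = rng.standard_normal(50)
        X = rng.standard_normal((50, 2))
        z = assign_groups(50, 0.5)
        y = apply_treatment_transform(y0, X, z, 1.0, 0.0, 0.0)
        assert np.array_equal(y, y0)

    def test_controls_untouched_bitwise(self, rng):
        y0 = rng.standard_normal(100)
        X = rng.standard_normal((100, 2))
        z = assign_groups(100, 0.5)
        y = apply_treatment_transform(y0, X, z, 2.0, 0.5, 0.0)
        assert np.array_equal(y[z == 0], y0[z == 0])

    def test_control_shift(self, rng):
        y0 = rng.standard_normal(20)
        z = assign_groups(20, 0.5)
        y = apply_treatment_transform(y0, np.empty((20, 0)), z, 1.0, 0.0, 0.7)
        assert np.allclose(y[z == 0] - y0[z == 0], 0.7)
        assert np.array_equal(y[z == 1], y0[z == 1])


class TestTheoreticalMoments:
    # printed group-2 variance/correlation for the five cases at rho=0.5, k=2
    @pytest.mark.parametrize("case,var,cor", [
        (1, 4.16, 0.71), (2, 2.75, 0.75), (3, 1.0, 0.5),
        (4, 2.0, 0.5), (5, 2.0, 0.5),
    ])
    def test_case_values(self, case, var, cor):
        _, v1, beta2 = CASES[case]
        v, c = theoretical_group2_moments(0.5, 2, v1, beta2)
        assert round(v, 2) == var
        assert round(c, 2) == cor

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.9])
    def test_null_transform(self, rho):
        assert theoretical_group2_moments(rho, 2, 1.0, 0.0) == (1.0, rho)


from hypothesis import given, settings, strategies as st


@given(rho=st.floats(0.0, 0.95), v1=st.floats(0.1, 5.0),
       beta2=st.floats(0.0, 2.0), k=st.integers(1, 2))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_theoretical_moments_are_a_valid_moment_pair(rho, v1, beta2, k):
    """The closed form always yields a positive variance and a
    correlation in [-1, 1] (it is cov/sqrt(var) by construction)."""
    var, cor = theoretical_group2_moments(rho, k, v1, beta2)
    assert var > 0
    assert -1.0 <= cor <= 1.0


class TestBaseSampling:
    @pytest.mark.parametrize("dist,rho", [
        ("normal", 0.0), ("normal", 0.5), ("normal", 0.9),
        ("t3", 0.0), ("t3", 0.5),
        ("lognormal", 0.0), ("lognormal", 0.5), ("lognormal", 0.9),
    ])
    def test_marginal_moments(self, dist, rho):
        n = 200_000
        sc = Scenario(dist=dist, rho=rho, n=n, k=2, delta=0.5)
        y0, X = sample_base(sc, np.random.default_rng(SEED))
        V = np.column_stack([y0, X])
        # t3 has infinite kurtosis: its sample variance converges slowly
        mean_tol, var_tol, cor_tol = ((0.02, 0.15, 0.05) if dist == "t3"
                                      else (0.01, 0.02, 0.01))
        assert np.abs(V.mean(axis=0)).max() < mean_tol
        assert np.abs(V.var(axis=0) - 1.0).max() < var_tol
        R = np.corrcoef(V.T)
        off = R[~np.eye(3, dtype=bool)]
        assert np.abs(off - rho).max() < cor_tol

    def test_lognormal_latent_solution(self):
        # unit variance requires e^{s2}(e^{s2}-1) = 1
        from gelrct.dgp import _lognormal_latent_cov
        L = _lognormal_latent_cov(3, 0.5)
        a = np.exp(L[0, 0])
        assert abs(a * (a - 1.0) - 1.0) < 1e-12
        assert abs(a * (np.exp(L[0, 1]) - 1.0) - 0.5) < 1e-12


class TestGroup2MomentsMC:
    @pytest.mark.parametrize("case", [1, 2, 4])
    def test_transform_matches_closed_form(self, case):
        delta, v1, beta2 = CASES[case]
        n = 200_000
        sc = Scenario(dist="normal", rho=0.5, delta=0.5, v1=v1, beta2=beta2,
                      n=n, k=2)
        d = sc.sample(np.random.default_rng(SEED + case))
        var_t, cor_t = theoretical_group2_moments(0.5, 2, v1, beta2)
        y1 = d.y[d.z == 1]
        X1 = d.X[d.z == 1]
        assert abs(y1.var() - var_t) < 0.06
        for j in range(2):
            assert abs(np.corrcoef(y1, X1[:, j])[0, 1] - cor_t) < 0.01


class TestPart3:
    def test_moments(self):
        d = sample_part3(0.8, 50_000, np.random.default_rng(SEED))
        diff = d.y[d.z == 0].mean() - d.y[d.z == 1].mean()
        # effect is expressed in outcome-SD units
        assert abs(diff - 0.8 * PART3_SD_Y) < 0.01
        assert abs(d.X.mean() - 1.07) < 0.01
        assert abs(np.corrcoef(d.y[d.z == 1], d.X[d.z == 1, 0])[0, 1]
                   - 0.35) < 0.015

    def test_null_effect(self):
        d = sample_part3(0.0, 50_000, np.random.default_rng(SEED))
        assert abs(d.y[d.z == 0].mean() - 1.82) < 0.01
        assert abs(d.y[d.z == 1].mean() - 1.82) < 0.01


class TestDeterminismAndIO:
    def test_sampling_is_pure(self):
        sc = Scenario(dist="lognormal", rho=0.5, k=2, seed=77)
        a, b = sc.sample(), sc.sample()
        assert np.array_equal(a.y, b.y) and np.array_equal(a.X, b.X)

    def test_yaml_roundtrip(self, tmp_path):
        sc = Scenario(dist="t3", rho=0.3, delta=0.2, v1=2.0, beta2=0.5,
                      n=200, k=2, seed=3)
        p = tmp_path / "scenario.yaml"
        sc.to_yaml(p)
        assert Scenario.from_yaml(p) == sc

    def test_csv_roundtrip(self, tmp_path, normal_k2):
        p = tmp_path / "trial.csv"
        normal_k2.to_csv(p)
        back = TrialData.from_csv(p)
        assert np.allclose(back.y, normal_k2.y)
        assert np.array_equal(back.z, normal_k2.z)
        assert np.allclose(back.X, normal_k2.X)

    @pytest.mark.parametrize("kwargs", [
        dict(delta=0.251, n=200),          # non-integral split
        dict(dist="cauchy"),               # unknown family
        dict(v1=0.0),                      # degenerate variance
    ])
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Scenario(**kwargs)
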