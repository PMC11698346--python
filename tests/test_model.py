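"""Vector field, equilibria and Jacobian of the double-Allee system."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracprey import (
    ModelParams,
    equilibria,
    generate_params,
    interior_equilibrium,
    jacobian,
    vector_field,
)
from fracprey.model import residual

from conftest import SET1, SET2, SET3

PRINTED_INTERIORS = [
    (SET1, (2.0543, 0.3970)),
    (SET2, (0.9689, 0.1349)),
    (SET3, (0.9824, 0.1600)),
]


class TestVectorField:
    def test_vanishes_at_published_interior(self):
        # the published coexistence point annihilates the rates
        f = vector_field(SET1, [2.0543, 0.3970])
        assert np.all(np.abs(f) < 1e-3)

    @pytest.mark.parametrize("p", [SET1, SET2, SET3])
    def test_origin_is_equilibrium(self, p):
        assert np.all(vector_field(p, [0.0, 0.0]) == 0.0)

    def test_matches_extended_precision_evaluation(self):
        # frozen from a 40-digit evaluation of the rate formulas (set1 at (1,1))
        f = vector_field(SET1, [1.0, 1.0])
        assert f[0] == pytest.approx(-0.43701619433198380567, rel=1e-13)
        assert f[1] == pytest.approx(-0.291, rel=1e-13)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(FloatingPointError):
            vector_field(SET1, [np.inf, 1.0])


class TestEquilibria:
    @pytest.mark.parametrize("p, expected", PRINTED_INTERIORS)
    def test_reproduces_published_interiors(self, p, expected):
        eq = interior_equilibrium(p)
        assert (round(eq.x1, 4), round(eq.x2, 4)) == expected

    @pytest.mark.parametrize("p", [SET1, SET2, SET3])
    def test_all_equilibria_annihilate_vector_field(self, p):
        for eq in equilibria(p):
            assert residual(p, eq) <= 1e-10

    def test_strong_regime_has_allee_point(self):
        kinds = {eq.kind for eq in equilibria(SET1)}
        assert kinds == {"extinction", "axial_carrying", "axial_allee", "interior"}

    def test_weak_regime_drops_allee_point(self):
        kinds = {eq.kind for eq in equilibria(SET3)}
        assert kinds == {"extinction", "axial_carrying", "interior"}

    def test_interior_prey_coordinate_is_predator_nullcline(self):
        # x1* = c/b is untouched by r, rho, alpha, beta
        base = interior_equilibrium(SET1).x1
        varied = SET1.replace(r=1.0, rho=5.0, alpha=0.1, beta=0.3)
        assert interior_equilibrium(varied).x1 == pytest.approx(base, abs=0.0)

    def test_interior_absent_when_mortality_too_high(self):
        p = SET1.replace(c=3.0)  # c/b = 10.87 > rho
        eq = interior_equilibrium(p)
        assert not eq.exists
        assert all(e.kind != "interior" for e in equilibria(p))

    def test_boundary_degenerate_interior_flagged(self):
        p = SET1.replace(c=SET1.b * SET1.rho)  # c/b == rho exactly
        eq = interior_equilibrium(p)
        assert eq.degenerate and not eq.exists


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 100_000), regime=st.sampled_from(["strong", "weak"]))
def test_equilibria_annihilate_field_on_random_admissible_params(seed, regime):
    """Every reported equilibrium of any admissible parameter set is a true
    steady state of the vector field."""
    p = generate_params(regime, seed=seed, n=1)[0]
    eqs = equilibria(p)
    assert any(eq.kind == "interior" for eq in eqs)
    for eq in eqs:
        assert residual(p, eq) <= 1e-10


class TestJacobian:
    def test_extinction_closed_form(self):
        # J(0,0) = diag(-alpha*r/beta, -c); first entry frozen from 40-digit arithmetic
        J = jacobian(SET1, [0.0, 0.0])
        assert J[0, 0] == pytest.approx(-0.20931687242798353909, rel=1e-13)
        assert J[1, 1] == pytest.approx(-0.567)
        assert J[0, 1] == 0.0 and J[1, 0] == 0.0

    @pytest.mark.parametrize("p", [SET1, SET2, SET3])
    def test_carrying_capacity_point_upper_triangular(self, p):
        J = jacobian(p, [p.rho, 0.0])
        assert J[1, 0] == 0.0
        assert J[1, 1] == pytest.approx(p.b * p.rho - p.c)
        expected_11 = p.r * p.rho / (p.rho + p.beta) * (p.alpha / p.rho - 1.0)
        assert J[0, 0] == pytest.approx(expected_11, rel=1e-12)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(42)
        eps = 1e-6
        for _ in range(20):
            s = rng.uniform(0.1, 5.0, size=2)
            J = jacobian(SET1, s)
            J_fd = np.empty((2, 2))
            for j in range(2):
                dp = s.copy()
                dm = s.copy()
                dp[j] += eps
                dm[j] -= eps
                J_fd[:, j] = (vector_field(SET1, dp) - vector_field(SET1, dm)) / (2 * eps)
            assert np.allclose(J, J_fd, rtol=1e-6, atol=1e-8)

    @pytest.mark.parametrize("p", [SET1, SET2, SET3])
    def test_interior_determinant_identity(self, p):
        # det J(interior) = a*b*x1*x2 > 0 whenever the point exists
        eq = interior_equilibrium(p)
        det = np.linalg.det(jacobian(p, eq.point))
        assert det == pytest.approx(p.a * p.b * eq.x1 * eq.x2, rel=1e-10)
        assert det > 0

    def test_interior_prey_entry_is_x1_times_g_prime(self):
        # s11 at the interior equals x1* g'(x1*) for g = prey growth per prey
        p = SET1
        eq = interior_equilibrium(p)

        def g(x):
            return p.r * (1 - x / p.rho) * (x - p.alpha) / (x + p.beta)

        eps = 1e-7
        gprime = (g(eq.x1 + eps) - g(eq.x1 - eps)) / (2 * eps)
        assert jacobian(p, eq.point)[0, 0] == pytest.approx(eq.x1 * gprime, rel=1e-6)


class TestModelParams:
    @pytest.mark.parametrize(
        "bad",
        [
            {"r": -0.1},
            {"rho": 0.0},
            {"beta": -1.0},
            {"alpha": -1.0},  # below -beta
            {"c": np.nan},
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        kwargs = SET1.to_dict()
        kwargs.update(bad)
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_alpha_at_minus_beta_boundary_allowed(self):
        # degenerate double-Allee boundary (factors cancel to logistic growth)
        p = SET3.replace(alpha=-0.5)
        assert p.regime == "weak"

    def test_regime_label(self):
        assert SET1.regime == "strong"
        assert SET3.regime == "weak"
        assert SET1.replace(alpha=0.0).regime == "weak"

    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_file_roundtrip(self, tmp_path, suffix):
        path = tmp_path / f"params{suffix}"
        SET1.to_file(path)
        assert ModelParams.from_file(path) == SET1

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelParams.from_dict({**SET1.to_dict(), "gamma": 1.0})

    def test_equilibrium_serialization_fields(self):
        d = interior_equilibrium(SET1).to_dict()
        assert set(d) == {"kind", "x1", "x2", "exists", "degenerate"}
        json.dumps(d)  # JSON-serializable
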