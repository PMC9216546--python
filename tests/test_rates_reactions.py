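"""Rate laws and the built-in example systems."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ratesnap as rs
from ratesnap.rates import (
    Constant,
    Hill,
    HillParams,
    MassActionDimer,
    hill_value,
    rate_law_from_dict,
)
from ratesnap.reactions import EXAMPLE_SYSTEMS, build_example_system, degradation_spec_for


class TestHill:
    def test_half_maximum_at_K(self):
        f = rs.hill_rate(HillParams(80, 2, 40))
        assert f(40) == pytest.approx(40.0)

    def test_saturates_at_lam(self):
        f = rs.hill_rate(HillParams(80, 2, 40))
        assert f(10**6) == pytest.approx(80.0, rel=1e-6)

    def test_zero_at_origin_for_activation(self):
        assert rs.hill_rate(HillParams(80, 2, 40))(0) == 0.0

    def test_repression_starts_at_lam(self):
        f = rs.hill_rate(HillParams(80, -2, 40))
        assert f(0) == pytest.approx(80.0)
        assert f(40) == pytest.approx(40.0)

    def test_zero_cooperativity_is_half_lam(self):
        f = rs.hill_rate(HillParams(80, 0, 40))
        assert np.all(f(np.arange(10)) == 40.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HillParams(80, 2, 0.0)
        with pytest.raises(ValueError):
            HillParams(-1, 2, 40)

    @given(
        lam=st.floats(0.1, 1e4),
        n=st.floats(-8, 8),
        K=st.floats(0.1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, lam, n, K):
        """f lies in [0, lam] and is monotone in the direction of n."""
        x = np.arange(0, 200)
        v = hill_value(x, lam, n, K)
        assert np.all(v >= 0) and np.all(v <= lam + 1e-9)
        d = np.diff(v[1:])  # x = 0 handled by convention, monotone from 1 up
        tol = 1e-12 * max(1.0, lam)  # float rounding at saturation
        if n > 0:
            assert np.all(d >= -tol)
        elif n < 0:
            assert np.all(d <= tol)


class TestExampleSystems:
    @pytest.mark.parametrize("name", EXAMPLE_SYSTEMS)
    def test_structure(self, name):
        sys_ = build_example_system(name)
        assert sys_.n_species == 3
        assert len(sys_.reactions) == 6  # 3 births + 3 deaths
        assert sys_.observed_pair == (1, 2)

    @pytest.mark.parametrize("name", EXAMPLE_SYSTEMS)
    def test_propensities_finite_nonnegative_on_grid(self, name):
        sys_ = build_example_system(name)
        grid = np.stack(
            np.meshgrid(np.arange(0, 201, 25), np.arange(0, 201, 25), np.arange(0, 201, 25)),
            axis=-1,
        ).reshape(-1, 3)
        p = sys_.propensities(grid)
        assert np.all(np.isfinite(p)) and np.all(p >= 0)

    def test_noise_enhancing_constant_birth(self):
        sys_ = build_example_system("noise_enhancing")
        f1 = sys_.reactions[0].propensity
        assert isinstance(f1, Constant) and f1.value == 5.0

    def test_dimeric_variant_removes_two(self):
        sys_ = build_example_system("noise_enhancing", degradation="dimeric")
        death = sys_.reactions[-1]
        assert death.stoich_change == (0, 0, -2)
        assert isinstance(death.propensity, MassActionDimer)
        # gamma=2: propensity 2*x3*(x3-1)
        assert death.propensity(np.array([0.0, 0.0, 7.0])) == pytest.approx(2 * 7 * 6)
        assert death.propensity(np.array([0.0, 0.0, 1.0])) == 0.0

    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="bistable"):
            build_example_system("nope")

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError, match="unknown override"):
            build_example_system("bistable", overrides={"zeta": 1.0})

    def test_deterministic_construction(self):
        a = build_example_system("oscillating")
        b = build_example_system("oscillating")
        assert a.to_dict() == b.to_dict()

    def test_lifetime_scaling_preserves_fixed_point(self):
        """tau2 rescales x2 birth and death together, leaving balance intact."""
        base = build_example_system("noise_enhancing")
        fast = build_example_system("noise_enhancing", overrides={"tau2": 0.1})
        x = np.array([5.0, 50.0, 46.0])
        pb, pf = base.propensities(x), fast.propensities(x)
        assert pf[2] == pytest.approx(10 * pb[2])  # birth scaled by 1/tau2
        assert pf[3] == pytest.approx(10 * pb[3])  # death scaled by 1/tau2
        assert pf[4] == pytest.approx(pb[4])       # conserved part untouched

    def test_degradation_spec_matches_system(self):
        lin = degradation_spec_for(build_example_system("bistable"))
        assert lin.step == 1 and lin.propensity(7) == pytest.approx(7.0)
        dim = degradation_spec_for(build_example_system("bistable", degradation="dimeric"))
        assert dim.step == 2 and dim.propensity(7) == pytest.approx(2 * 7 * 6)
        assert dim.propensity(np.array([0.0, 1.0])).max() == 0.0


class TestSerialization:
    @pytest.mark.parametrize("name", EXAMPLE_SYSTEMS)
    def test_yaml_round_trip(self, name, tmp_path):
        sys_ = build_example_system(name, degradation="dimeric" if name[0] == "n" else "linear")
        path = tmp_path / "system.yaml"
        sys_.to_yaml(path)
        back = rs.ReactionSystem.from_yaml(path)
        assert back.to_dict() == sys_.to_dict()
        x = np.array([3.0, 20.0, 15.0])
        assert np.allclose(back.propensities(x), sys_.propensities(x))

    def test_rate_law_dict_round_trip(self):
        law = Hill(HillParams(12, -3, 7.5), species=2)
        assert rate_law_from_dict(law.to_dict()) == law

    def test_degradation_spec_validation(self):
        with pytest.raises(ValueError):
            rs.DegradationSpec.linear(tau3=0.0)
        with pytest.raises(ValueError):
            rs.DegradationSpec.dimeric(gamma=-1.0)
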