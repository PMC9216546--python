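"""Balance assembly and the regularized non-negative inversion."""

import numpy as np
import pytest

import ratesnap as rs
from ratesnap.distributions import empirical_joint
from ratesnap.inference import kkt_violation, second_difference_matrix


@pytest.fixture(scope="module")
def poisson_balance(poisson_oracle, linear_degradation):
    joint = poisson_oracle.joint_observed((0, 1))
    return rs.assemble_balance_system(joint, linear_degradation)


class TestAssembly:
    def test_row_sums_equal_x3_marginal(self, reduced_joint, linear_degradation):
        bal = rs.assemble_balance_system(reduced_joint, linear_degradation)
        assert np.allclose(bal.G.sum(axis=1), reduced_joint.p_x3()[: len(bal.row_states)])

    def test_boundary_rows_dropped(self, reduced_joint, linear_degradation):
        bal = rs.assemble_balance_system(reduced_joint, linear_degradation)
        assert len(bal.row_states) == len(reduced_joint.x3_values) - 1
        bal2 = rs.assemble_balance_system(reduced_joint, rs.DegradationSpec.dimeric(2.0))
        assert len(bal2.row_states) == len(reduced_joint.x3_values) - 2

    def test_linear_h_is_shifted_weighted_marginal(self, poisson_balance, poisson_oracle):
        p3 = poisson_oracle.marginal(1)
        m = np.arange(len(poisson_balance.h))
        assert np.allclose(poisson_balance.h, (m + 1) * p3[1 : len(m) + 1])

    def test_dimeric_h_hand_computed(self):
        """Four-level x3 distribution, gamma = 2: cut fluxes by hand."""
        p3 = np.array([0.4, 0.3, 0.2, 0.1])
        joint = rs.JointDistribution(np.array([0]), np.arange(4), p3[None, :])
        gamma = 2.0
        bal = rs.assemble_balance_system(joint, rs.DegradationSpec.dimeric(gamma))
        h0 = gamma * 1 * 0 * p3[1] + gamma * 2 * 1 * p3[2]
        h1 = gamma * 2 * 1 * p3[2] + gamma * 3 * 2 * p3[3]
        assert bal.h == pytest.approx([h0, h1])

    def test_empty_joint_rejected(self, linear_degradation):
        tiny = rs.JointDistribution(np.array([0]), np.array([0]), np.array([[1.0]]))
        with pytest.raises(ValueError):
            rs.assemble_balance_system(tiny, linear_degradation)


class TestInferRate:
    def test_poisson_constant_recovered_exactly(self, poisson_balance):
        est = rs.infer_rate(poisson_balance, epsilon=1e-12)
        assert est.f_values == pytest.approx([5.0], rel=1e-8)

    def test_oracle_equivalence_two_percent(self, reduced_joint, reduced_true_rate,
                                            linear_degradation):
        """Exact input at floor regularization recovers the generating Hill
        rate to <2% on every non-negligible state."""
        bal = rs.assemble_balance_system(reduced_joint, linear_degradation)
        est = rs.infer_rate(bal, epsilon=1e-12)
        tv = reduced_true_rate(est.x2_states)
        mask = (est.reliability > 1e-3) & (tv > 0)
        rel = np.abs(est.f_values[mask] - tv[mask]) / tv[mask]
        assert rel.max() < 0.02

    def test_huge_epsilon_drives_affine_limit(self, reduced_ensemble, linear_degradation):
        bal = rs.assemble_balance_system(empirical_joint(reduced_ensemble), linear_degradation)
        est = rs.infer_rate(bal, epsilon=1e6)
        curvature = second_difference_matrix(len(est.f_values)) @ est.f_values
        assert np.abs(curvature).max() < 1e-3 * max(1.0, est.f_values.max())

    def test_kkt_optimality(self, reduced_ensemble, linear_degradation):
        bal = rs.assemble_balance_system(empirical_joint(reduced_ensemble), linear_degradation)
        est = rs.infer_rate(bal)
        assert kkt_violation(bal, est) < 1e-8

    def test_monotone_constraint_respected(self, reduced_ensemble, linear_degradation):
        bal = rs.assemble_balance_system(empirical_joint(reduced_ensemble), linear_degradation)
        up = rs.infer_rate(bal, extra_constraints="monotone_up")
        assert np.all(np.diff(up.f_values) >= -1e-9)
        down = rs.infer_rate(bal, extra_constraints="monotone_down")
        assert np.all(np.diff(down.f_values) <= 1e-9)

    def test_scale_unidentifiability(self, reduced_ensemble):
        """Scaling the degradation rate by c scales f by exactly c; the
        normalized shape is invariant."""
        joint = empirical_joint(reduced_ensemble)
        a = rs.infer_rate(rs.assemble_balance_system(joint, rs.DegradationSpec.linear(1.0)))
        b = rs.infer_rate(
            rs.assemble_balance_system(joint, rs.DegradationSpec.linear(1.0 / 3.0)),
            epsilon=a.epsilon,
        )
        assert np.allclose(b.f_values, 3.0 * a.f_values, rtol=1e-9, atol=1e-9)

    def test_invalid_epsilon(self, poisson_balance):
        with pytest.raises(ValueError):
            rs.infer_rate(poisson_balance, epsilon=-1.0)


class TestEpsilonHeuristic:
    def test_positive_and_strictly_decreasing(self):
        ns = np.array([10, 10**3, 10**5, 10**7])
        for policy in ("one_over_sqrt_n", "one_over_n"):
            eps = np.array([rs.default_epsilon(int(n), policy) for n in ns])
            assert np.all(eps > 0)
            assert np.all(np.diff(eps) < 0)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            rs.default_epsilon(0)


class TestConstantFit:
    def test_poisson_exact(self, poisson_balance):
        lam, resid = rs.fit_constant_rate(poisson_balance)
        assert lam == pytest.approx(5.0, rel=1e-10)
        assert resid < 1e-20

    def test_zero_h_gives_zero(self):
        bal = rs.BalanceSystem(
            G=np.array([[0.5, 0.5]]), h=np.array([0.0]),
            col_states=np.array([0, 1]), row_states=np.array([0]),
            p_x2=np.array([0.5, 0.5]),
        )
        lam, _ = rs.fit_constant_rate(bal)
        assert lam == 0.0

    def test_free_fit_beats_constant_on_varying_rate(self, reduced_ensemble,
                                                     linear_degradation):
        bal = rs.assemble_balance_system(empirical_joint(reduced_ensemble), linear_degradation)
        _, resid_const = rs.fit_constant_rate(bal)
        free = rs.infer_rate(bal, epsilon=1e-12)
        resid_free = float(np.sum((bal.G @ free.f_values - bal.h) ** 2))
        assert resid_free < resid_const


class TestCrossValidation:
    def test_deterministic_given_split_seed(self, reduced_ensemble, linear_degradation):
        a = rs.infer_rate_cv(reduced_ensemble, linear_degradation, split_seed=4)
        b = rs.infer_rate_cv(reduced_ensemble, linear_degradation, split_seed=4)
        assert a.model == b.model
        assert np.array_equal(a.f_values, b.f_values)

    def test_needs_two_samples(self, linear_degradation):
        ens = rs.SnapshotEnsemble(np.array([[1, 1]]))
        with pytest.raises(ValueError):
            rs.infer_rate_cv(ens, linear_degradation)
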