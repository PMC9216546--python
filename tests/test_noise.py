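"""Measurement-noise models and the undercounting correction."""

import numpy as np
import pytest
from scipy.stats import poisson

import ratesnap as rs
from ratesnap.distributions import empirical_joint


@pytest.fixture(scope="module")
def clean(reduced_joint):
    return reduced_joint.sample(40_000, seed=31)


class TestIdentities:
    def test_zero_sigma_and_unit_p_are_identities(self, clean):
        for out in (
            rs.apply_additive(clean, 0.0, seed=1),
            rs.apply_relative(clean, 0.0, seed=1),
            rs.apply_undercount(clean, 1.0, seed=1),
            rs.correct_undercount(clean, 1.0),
        ):
            assert np.array_equal(out.samples, clean.samples)

    def test_invalid_parameters(self, clean):
        with pytest.raises(ValueError):
            rs.apply_additive(clean, -1.0, seed=1)
        with pytest.raises(ValueError):
            rs.apply_undercount(clean, 0.0, seed=1)
        with pytest.raises(ValueError):
            rs.NoiseSpec(kind="additive", sigma_rel=0.1)
        with pytest.raises(ValueError):
            rs.NoiseSpec(kind="bogus", sigma_abs=1.0)


class TestCorruption:
    def test_additive_increases_variance(self, clean):
        noisy = rs.apply_additive(clean, 8.0, seed=2)
        assert noisy.x3.astype(float).var() > clean.x3.astype(float).var()
        assert noisy.samples.min() >= 0
        assert noisy.meta["n_discarded"] >= 0

    def test_additive_small_sigma_preserves_mean_when_discards_few(self):
        """Away from the origin (counts ~25, sigma 3) nothing is discarded
        and the corrupted mean matches the clean mean to Monte-Carlo error;
        near the origin the documented discard bias appears."""
        far = rs.SnapshotEnsemble(np.random.default_rng(1).poisson(25.0, size=(40_000, 2)))
        noisy = rs.apply_additive(far, 3.0, seed=2)
        assert noisy.meta["n_discarded"] == 0
        se = far.x3.std() / np.sqrt(far.n)
        assert abs(noisy.x3.mean() - far.x3.mean()) < 4 * se

    def test_additive_discard_bias_near_origin(self, clean):
        # the reduced system has ~11% of its x3 mass at <= 2 molecules, so
        # sigma = 3 discards a few percent and biases the mean upward
        noisy = rs.apply_additive(clean, 3.0, seed=2)
        assert noisy.meta["n_discarded"] > 0
        assert 0 < noisy.x3.mean() - clean.x3.mean() < 1.5

    def test_relative_corruption_grows_with_sigma(self, clean):
        """Total-variation distortion of the joint is monotone in sigma_rel."""

        def tv_from_clean(sig):
            noisy = rs.apply_relative(clean, sig, seed=3)
            a, b = empirical_joint(clean), empirical_joint(noisy)
            hi2 = max(a.x2_values.max(), b.x2_values.max()) + 1
            hi3 = max(a.x3_values.max(), b.x3_values.max()) + 1
            pa, pb = np.zeros((hi2, hi3)), np.zeros((hi2, hi3))
            pa[np.ix_(a.x2_values, a.x3_values)] = a.prob
            pb[np.ix_(b.x2_values, b.x3_values)] = b.prob
            return 0.5 * np.abs(pa - pb).sum()

        assert tv_from_clean(0.2) > tv_from_clean(0.01)

    def test_undercount_halves_means(self, clean):
        thin = rs.apply_undercount(clean, 0.5, seed=4)
        assert thin.x2.mean() == pytest.approx(0.5 * clean.x2.mean(), rel=0.03)
        assert thin.x3.mean() == pytest.approx(0.5 * clean.x3.mean(), rel=0.03)
        assert thin.n == clean.n  # no discards ever

    def test_poisson_thinning_closure(self):
        """Thinning Poisson(10) at p=0.5 gives Poisson(5) (distributional)."""
        rng_samples = np.random.default_rng(9).poisson(10.0, size=(60_000, 2))
        ens = rs.SnapshotEnsemble(rng_samples)
        thin = rs.apply_undercount(ens, 0.5, seed=5)
        emp = np.bincount(thin.x3, minlength=20)[:20] / thin.n
        assert np.abs(emp - poisson.pmf(np.arange(20), 5.0)).max() < 0.01


class TestUndercountCorrection:
    def test_mean_restored_in_expectation(self, clean):
        thin = rs.apply_undercount(clean, 0.5, seed=6)
        fixed = rs.correct_undercount(thin, 0.5)
        assert fixed.x2.mean() == pytest.approx(clean.x2.mean(), rel=0.02)

    def test_estimate_axis_rescaled(self):
        est = rs.RateEstimate(
            x2_states=np.array([0, 1, 2]), f_values=np.array([1.0, 2.0, 3.0]),
            epsilon=0.0, reliability=np.ones(3),
        )
        fixed = rs.correct_undercount(est, 0.5)
        assert list(fixed.x2_states) == [0, 2, 4]
        assert np.array_equal(fixed.f_values, est.f_values)

    def test_joint_correction_merges_and_normalizes(self, clean):
        joint = empirical_joint(rs.apply_undercount(clean, 0.7, seed=7))
        fixed = rs.correct_undercount(joint, 0.7)
        assert fixed.prob.sum() == pytest.approx(1.0, abs=1e-12)

    def test_corrected_inference_recovers_rate(self, clean, reduced_true_rate,
                                               linear_degradation):
        """p = 0.5 thinning + 1/p correction: inferred rate stays close to
        the truth at the correct scale (exactness of the correction for
        first-order degradation)."""
        thin = rs.apply_undercount(clean, 0.5, seed=8)
        fixed = rs.correct_undercount(thin, 0.5)
        deg = rs.undercount_degradation(linear_degradation, 0.5)
        est = rs.infer_rate(rs.assemble_balance_system(empirical_joint(fixed), deg))
        E = rs.inference_error(est, reduced_true_rate).E
        clean_est = rs.infer_rate(
            rs.assemble_balance_system(empirical_joint(clean), linear_degradation)
        )
        E_clean = rs.inference_error(clean_est, reduced_true_rate).E
        assert E < max(2.0 * E_clean, 0.05)
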