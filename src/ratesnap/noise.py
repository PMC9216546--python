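"""Measurement-noise models for snapshot ensembles, and the undercount fix.

Three corruption channels mimic common single-cell measurement artifacts:

* additive  -- independent zero-mean Gaussians of sd ``sigma_abs`` molecules
  on each coordinate, rounded to integers; samples driven negative are
  discarded and the ensemble renormalized.
* relative  -- each coordinate multiplied by an independent Normal(1,
  sigma_rel) draw, same rounding/discard policy.
* undercount -- each molecule independently detected with probability p,
  i.e. Binomial(value, p) thinning per coordinate; never negative.

Rounding to the nearest integer is applied because the balance equations
live on discrete states; the "two-dimensional Gaussian" is read as
independent per-coordinate noise (no cross-correlation).

Undercounting is the one channel with an exact correction when the species
of interest degrades in first order.  Molecules detected with probability p
form a birth-death process of their own: births arrive at rate p*f(x2_true)
and each detected molecule still dies at rate 1/tau3.  The measured x3 axis
therefore satisfies unit-step balance equations as-is; what needs undoing
is (a) the x2 axis, rescaled by 1/p to approximate the true regulator
abundance, and (b) the degradation rate, evaluated at the true abundance
m/p rather than the detected count m (for linear degradation this is the
factor 1/p that also cancels the production thinning, making the recovered
rate exactly f rather than p*f).  ``correct_undercount`` rescales the x2
axis; ``undercount_degradation`` builds the matching degradation spec.  If
p is unknown the shape of f is still recovered, just over an unknown
rescaling of the x2 axis and an unknown rate scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import JointDistribution
from .inference import RateEstimate
from .reactions import DegradationSpec
from .ssa import SnapshotEnsemble

__all__ = [
    "NoiseSpec",
    "apply_noise",
    "apply_additive",
    "apply_relative",
    "apply_undercount",
    "correct_undercount",
]


@dataclass(frozen=True)
class NoiseSpec:
    kind: str  # additive | relative | undercount
    sigma_abs: float | None = None
    sigma_rel: float | None = None
    p_detect: float | None = None
    seed: int = 0

    def __post_init__(self):
        expected = {"additive": "sigma_abs", "relative": "sigma_rel", "undercount": "p_detect"}
        if self.kind not in expected:
            raise ValueError(f"kind must be one of {sorted(expected)}")
        set_fields = {
            k for k in ("sigma_abs", "sigma_rel", "p_detect") if getattr(self, k) is not None
        }
        if set_fields != {expected[self.kind]}:
            raise ValueError(f"noise kind {self.kind!r} requires exactly {expected[self.kind]}")
        if self.kind == "undercount" and not (0 < self.p_detect <= 1):
            raise ValueError("p_detect must be in (0, 1]")


def apply_noise(samples: SnapshotEnsemble, spec: NoiseSpec) -> SnapshotEnsemble:
    if spec.kind == "additive":
        return apply_additive(samples, spec.sigma_abs, spec.seed)
    if spec.kind == "relative":
        return apply_relative(samples, spec.sigma_rel, spec.seed)
    return apply_undercount(samples, spec.p_detect, spec.seed)


def _finish(values: np.ndarray, samples: SnapshotEnsemble, extra_meta: dict) -> SnapshotEnsemble:
    rounded = np.round(values).astype(np.int64)
    keep = np.all(rounded >= 0, axis=1)
    if not keep.any():
        raise ValueError("all samples discarded by the noise model")
    meta = dict(samples.meta)
    meta.update(extra_meta)
    meta["n_discarded"] = int((~keep).sum())
    return SnapshotEnsemble(samples=rounded[keep], meta=meta)


def apply_additive(samples: SnapshotEnsemble, sigma_abs: float, seed: int) -> SnapshotEnsemble:
    """Gaussian additive noise; negatives discarded, count of discards in meta."""
    if sigma_abs < 0:
        raise ValueError("sigma_abs must be >= 0")
    if sigma_abs == 0:
        return SnapshotEnsemble(samples.samples.copy(), meta=dict(samples.meta))
    rng = np.random.default_rng(seed)
    noisy = samples.samples + rng.normal(0.0, sigma_abs, size=samples.samples.shape)
    return _finish(noisy, samples, {"noise": "additive", "sigma_abs": sigma_abs, "noise_seed": seed})


def apply_relative(samples: SnapshotEnsemble, sigma_rel: float, seed: int) -> SnapshotEnsemble:
    """Multiplicative Normal(1, sigma_rel) noise; same discard policy."""
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be >= 0")
    if sigma_rel == 0:
        return SnapshotEnsemble(samples.samples.copy(), meta=dict(samples.meta))
    rng = np.random.default_rng(seed)
    noisy = samples.samples * rng.normal(1.0, sigma_rel, size=samples.samples.shape)
    return _finish(noisy, samples, {"noise": "relative", "sigma_rel": sigma_rel, "noise_seed": seed})


def apply_undercount(samples: SnapshotEnsemble, p_detect: float, seed: int) -> SnapshotEnsemble:
    """Binomial thinning: each molecule detected with probability p."""
    if not (0 < p_detect <= 1):
        raise ValueError("p_detect must be in (0, 1]")
    if p_detect == 1:
        return SnapshotEnsemble(samples.samples.copy(), meta=dict(samples.meta))
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(samples.samples, p_detect)
    meta = dict(samples.meta)
    meta.update({"noise": "undercount", "p_detect": p_detect, "noise_seed": seed})
    return SnapshotEnsemble(samples=thinned, meta=meta)


def _rescale_axis(values: np.ndarray, p: float) -> np.ndarray:
    return np.round(values / p).astype(np.int64)


def correct_undercount(obj, p_detect: float):
    """Undo binomial undercounting by rescaling the measured x2 axis by 1/p.

    * SnapshotEnsemble / JointDistribution: x2 coordinate (support) mapped
      to the nearest integer of x2/p; colliding joint states (possible for
      non-integer 1/p) have their probabilities merged.  The x3 axis is
      intentionally left on the measured grid -- pair the corrected object
      with :func:`undercount_degradation` when assembling balance
      equations so the degradation rate refers to the true abundance.
    * RateEstimate: x2 states rescaled, rate values untouched.

    With p = 1 every branch is the identity.
    """
    if not (0 < p_detect <= 1):
        raise ValueError("p_detect must be in (0, 1]")
    if isinstance(obj, SnapshotEnsemble):
        fixed = obj.samples.copy()
        fixed[:, 0] = _rescale_axis(fixed[:, 0], p_detect)
        return SnapshotEnsemble(fixed, meta={**obj.meta, "undercount_corrected": p_detect})
    if isinstance(obj, RateEstimate):
        return RateEstimate(
            x2_states=_rescale_axis(obj.x2_states, p_detect),
            f_values=obj.f_values.copy(),
            epsilon=obj.epsilon,
            scale_known=obj.scale_known,
            model=obj.model,
            objective=obj.objective,
            reliability=None if obj.reliability is None else obj.reliability.copy(),
            meta={**obj.meta, "undercount_corrected": p_detect},
        )
    if isinstance(obj, JointDistribution):
        new_x2 = _rescale_axis(obj.x2_values, p_detect)
        grid2 = np.arange(new_x2.min(), new_x2.max() + 1)
        mat = np.zeros((len(grid2), len(obj.x3_values)))
        np.add.at(mat, new_x2 - grid2[0], obj.prob)
        return JointDistribution(
            grid2, obj.x3_values.copy(), mat / mat.sum(), n_source_samples=obj.n_source_samples
        )
    raise TypeError("correct_undercount expects an ensemble, joint, or estimate")


def undercount_degradation(original: DegradationSpec, p_detect: float) -> DegradationSpec:
    """Degradation spec for balance assembly on undercounted x3 data.

    The detected count m corresponds to a true abundance of about m/p, so
    the per-event rate becomes ``original.propensity(m / p)`` while the
    step stays in detected units.  Exact for linear degradation (detected
    molecules die independently); approximate for the dimeric channel.
    """
    if not (0 < p_detect <= 1):
        raise ValueError("p_detect must be in (0, 1]")
    g0 = original.propensity

    def g(x):
        return g0(np.asarray(x, dtype=float) / p_detect)

    return DegradationSpec(
        step=original.step,
        propensity=g,
        scale_known=original.scale_known,
        label=f"{original.label}_undercount",
    )
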