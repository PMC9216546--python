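"""Quality metrics: the weighted inference error E and the importance I.

E is the probability-weighted absolute deviation between inferred and true
rate, normalized by the mean true rate under the same weights:

    E = sum_x2 |f_inf(x2) - f_true(x2)| P(x2) / <f_true>.

States never observed carry P(x2) = 0 and drop out automatically.

I measures how much of the downstream variable's squared coefficient of
variation is attributable to covariation with its regulator.  For any
system where X3 is produced at rate f(x2) and degraded linearly, the
stationary moments obey the noise-propagation identity

    Var(x3)/<x3>^2 = 1/<x3> + Cov(x3, f(x2)) / (<x3> <f>)

and I := |eta_x3f| / eta_x3x3 with eta_x3f the covariance term and
eta_x3x3 the left-hand side.  Small I predicts poor inferability: the data
simply do not carry much information about f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import JointDistribution
from .inference import RateEstimate
from .ssa import SnapshotEnsemble

__all__ = ["ErrorReport", "ImportanceReport", "inference_error", "importance"]


@dataclass
class ErrorReport:
    E: float
    per_state_abs_error: np.ndarray
    x2_states: np.ndarray
    mean_true_rate: float


@dataclass
class ImportanceReport:
    eta_x3x3: float   # CV^2 of x3
    eta_x3f: float    # Cov(x3, f(x2)) / (<x3> <f>)
    I: float
    flux_residual: float  # eta_x3x3 - 1/<x3> - eta_x3f; ~0 for linear degradation
    mean_x3: float
    mean_f: float


def inference_error(
    f_inferred: RateEstimate, f_true, p_x2: np.ndarray | None = None
) -> ErrorReport:
    """Evaluate E for an estimate against the true rate function.

    ``f_true`` is a callable on integer x2 states.  Weights default to the
    estimate's own reliability vector (the empirical P(x2) of the data it
    was fitted on).
    """
    if p_x2 is None:
        p_x2 = f_inferred.reliability
    p = np.asarray(p_x2, dtype=float)
    if p.shape != f_inferred.x2_states.shape:
        raise ValueError("weight vector must align with the estimate's states")
    true_vals = np.asarray(f_true(f_inferred.x2_states), dtype=float)
    mean_true = float(true_vals @ p)
    if mean_true <= 0:
        raise ValueError("mean true rate is zero under these weights; E undefined")
    abs_err = np.abs(f_inferred.f_values - true_vals)
    E = float(abs_err @ p / mean_true)
    return ErrorReport(
        E=E, per_state_abs_error=abs_err, x2_states=f_inferred.x2_states.copy(),
        mean_true_rate=mean_true,
    )


def importance(samples_or_joint, f, degradation_scale: float = 1.0) -> ImportanceReport:
    """Importance I and the flux-relation residual from snapshot moments.

    ``f`` is the (true or inferred) production-rate function of x2;
    ``degradation_scale`` rescales 1/<x3> for a known non-unit lifetime
    convention (kept at 1 for the built-in tau3=1 systems).  Plain sample
    moments are used; intended for large N.
    """
    if isinstance(samples_or_joint, SnapshotEnsemble):
        x2 = samples_or_joint.x2.astype(float)
        x3 = samples_or_joint.x3.astype(float)
        fv = np.asarray(f(x2), dtype=float)
        mean_x3, var_x3 = float(x3.mean()), float(x3.var())
        mean_f = float(fv.mean())
        cov = float(np.mean((x3 - mean_x3) * (fv - mean_f)))
    elif isinstance(samples_or_joint, JointDistribution):
        joint = samples_or_joint
        mom = joint.moments()
        mean_x3, var_x3 = mom["mean_x3"], mom["var_x3"]
        fv = np.asarray(f(joint.x2_values), dtype=float)
        p2 = joint.p_x2()
        mean_f = float(fv @ p2)
        flux_x3 = joint.prob @ joint.x3_values.astype(float)  # sum_x3 x3 P(x2, x3)
        cov = float((fv - mean_f) @ (flux_x3 - p2 * mean_x3))
    else:
        raise TypeError("expected SnapshotEnsemble or JointDistribution")
    if var_x3 <= 0:
        raise ValueError("x3 is degenerate; importance undefined")
    if mean_x3 <= 0 or mean_f <= 0:
        raise ValueError("importance needs positive mean x3 and mean f")
    eta33 = var_x3 / mean_x3**2
    eta3f = cov / (mean_x3 * mean_f)
    residual = eta33 - degradation_scale / mean_x3 - eta3f
    return ImportanceReport(
        eta_x3x3=eta33, eta_x3f=eta3f, I=abs(eta3f) / eta33,
        flux_residual=residual, mean_x3=mean_x3, mean_f=mean_f,
    )


def shape_distance(a: RateEstimate, b: RateEstimate, min_reliability: float = 1e-3):
    """E-style distance between two estimates on jointly reliable states.

    Compares the two tables only where *both* carry empirical weight above
    ``min_reliability`` (elsewhere at least one value is a smoothness
    interpolation, not an inference).  Weighted by the averaged marginals
    and normalized by the weighted mean level, mirroring E.  Returns
    ``(distance, overlap_mass)``; the distance is NaN when the reliable
    supports do not overlap, and the overlap mass tells the caller how much
    probability the comparison actually covered.
    """
    lo = max(a.x2_states.min(), b.x2_states.min())
    hi = min(a.x2_states.max(), b.x2_states.max())
    if lo > hi:
        return float("nan"), 0.0
    states = np.arange(lo, hi + 1)

    def on(est, arr):
        return arr[np.searchsorted(est.x2_states, states)]

    fa, fb = on(a, a.f_values), on(b, b.f_values)
    ra, rb = on(a, a.reliability), on(b, b.reliability)
    mask = (ra > min_reliability) & (rb > min_reliability)
    overlap = float(np.minimum(ra, rb)[mask].sum())
    if not mask.any():
        return float("nan"), 0.0
    w = 0.5 * (ra + rb) * mask
    w = w / w.sum()
    level = float(0.5 * (fa + fb) @ w)
    if level <= 0:
        return float("nan"), overlap
    return float(np.abs(fa - fb) @ w / level), overlap
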