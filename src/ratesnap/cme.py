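"""Brute-force stationary solver for small truncated master equations.

This is the package's independent oracle: for systems whose reachable state
space fits in a modest box it computes the exact stationary distribution by
a sparse null-space solve of the truncated generator, against which both the
simulator and the inference layer are cross-checked.  It is deliberately not
a scalable CME method -- its job is ground truth on small instances.

Truncation convention: any reaction that would leave the box has its
propensity set to zero at the offending states (a reflecting boundary), so
the truncated generator remains a proper rate matrix.  The total probability
on boundary faces is reported as ``leaked_mass``; a solve is trustworthy
only when that mass is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .distributions import JointDistribution
from .reactions import ReactionSystem

__all__ = ["TruncatedStationaryDistribution", "solve_stationary"]

_MAX_STATES = 2_000_000


@dataclass
class TruncatedStationaryDistribution:
    """Stationary probabilities on the box prod_i {0..bounds[i]}."""

    bounds: tuple[int, ...]
    probabilities: np.ndarray  # shape bounds+1, sums to 1
    leaked_mass: float
    system_name: str = ""

    def marginal(self, species: int) -> np.ndarray:
        axes = tuple(a for a in range(self.probabilities.ndim) if a != species)
        return self.probabilities.sum(axis=axes)

    def joint_observed(self, observed_pair=(1, 2), trim_tol: float = 0.0) -> JointDistribution:
        """Marginalize onto the observed pair as a JointDistribution.

        ``trim_tol`` drops trailing support rows/columns whose total mass is
        below the tolerance (the far tail of the box), keeping grids small.
        """
        i, j = observed_pair
        axes = tuple(a for a in range(self.probabilities.ndim) if a not in (i, j))
        mat = self.probabilities.sum(axis=axes)
        if i > j:
            mat = mat.T
        hi2, hi3 = mat.shape
        if trim_tol > 0:
            p2, p3 = mat.sum(axis=1), mat.sum(axis=0)
            hi2 = int(np.nonzero(p2 > trim_tol)[0].max()) + 1
            hi3 = int(np.nonzero(p3 > trim_tol)[0].max()) + 1
            mat = mat[:hi2, :hi3]
        mat = np.clip(mat, 0.0, None)
        return JointDistribution(
            np.arange(hi2), np.arange(hi3), mat / mat.sum(), n_source_samples=0
        )


def _state_grid(bounds):
    shape = tuple(b + 1 for b in bounds)
    grids = np.indices(shape)  # (ns, *shape)
    return np.stack([g.ravel() for g in grids], axis=-1), shape


def solve_stationary(system: ReactionSystem, bounds) -> TruncatedStationaryDistribution:
    """Exact stationary distribution of the truncated generator.

    ``bounds`` gives the per-species maximum count.  Raises if the box
    exceeds ~2e6 states or if the linear solve degenerates (e.g. the chain
    is reducible within the box).
    """
    bounds = tuple(int(b) for b in bounds)
    if len(bounds) != system.n_species:
        raise ValueError("one bound per species required")
    n_states = int(np.prod([b + 1 for b in bounds]))
    if n_states > _MAX_STATES:
        raise ValueError(f"truncated space has {n_states} states (max {_MAX_STATES})")

    states, shape = _state_grid(bounds)
    strides = np.array([int(np.prod(shape[k + 1:])) for k in range(len(shape))], dtype=np.int64)

    rows_idx: list[np.ndarray] = []
    cols_idx: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n_states)
    src = np.arange(n_states, dtype=np.int64)
    for rx in system.reactions:
        rates = np.asarray(rx.propensity(states.astype(float)), dtype=float).ravel()
        if np.any(rates < 0) or not np.all(np.isfinite(rates)):
            raise ValueError("propensity produced negative or non-finite rates")
        d = np.asarray(rx.stoich_change, dtype=np.int64)
        target_states = states + d
        inside = np.all((target_states >= 0) & (target_states <= np.array(bounds)), axis=1)
        keep = inside & (rates > 0)
        tgt = src[keep] + d @ strides
        rows_idx.append(tgt)
        cols_idx.append(src[keep])
        vals.append(rates[keep])
        diag[keep] -= rates[keep]  # exiting reactions reflected: no outflow added

    # generator A with A[i,j] = rate j->i (i != j), A[j,j] = -sum outflow
    A = sp.coo_matrix(
        (
            np.concatenate(vals + [diag]),
            (np.concatenate(rows_idx + [src]), np.concatenate(cols_idx + [src])),
        ),
        shape=(n_states, n_states),
    ).tocsr()

    # Null space via anchoring: fix pi = 1 at a high-probability reference
    # state (the deterministic rate-balance point, clipped into the box),
    # drop that row/column, solve the remaining nonsingular sparse system,
    # then normalize.  Anchoring near the mode keeps the relative values in
    # floating-point range; anchoring at a remote corner would not.
    from .ssa import deterministic_fixed_point  # local import: no cycle at module load

    ref = np.minimum(deterministic_fixed_point(system), np.array(bounds))
    anchor = int(ref @ strides)
    keep_idx = np.concatenate([np.arange(anchor), np.arange(anchor + 1, n_states)])
    A = A.tocsc()
    rhs = -np.asarray(A[:, anchor].todense()).ravel()[keep_idx]
    A_red = A[keep_idx][:, keep_idx]
    try:
        x = spla.spsolve(A_red.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - solver backend specific
        raise RuntimeError(f"stationary solve failed: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise RuntimeError("stationary solve returned non-finite probabilities")
    pi = np.empty(n_states)
    pi[keep_idx] = x
    pi[anchor] = 1.0
    scale = pi.sum()
    if pi.min() < -1e-8 * scale:
        raise RuntimeError(
            f"stationary solve numerically singular (min prob {pi.min() / scale:.3g})"
        )
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    P = pi.reshape(shape)
    on_boundary = np.zeros(shape, dtype=bool)
    for ax, bmax in enumerate(bounds):
        if bmax == 0:  # pinned species: the face is the whole box, not a truncation
            continue
        sl = [slice(None)] * len(shape)
        sl[ax] = bmax
        on_boundary[tuple(sl)] = True
    leaked = float(P[on_boundary].sum())
    return TruncatedStationaryDistribution(
        bounds=bounds, probabilities=P, leaked_mass=leaked, system_name=system.name
    )
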