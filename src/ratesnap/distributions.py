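"""Empirical and exact joint distributions P(x2, x3).

Supports are stored as full integer ranges [min, max] per axis with explicit
zeros inside the hull, so that downstream balance matrices have well-defined
columns for interior states that happened never to be observed; rates at
such states are penalty-interpolated and flagged unreliable by the inference
layer rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ssa import SnapshotEnsemble

__all__ = ["JointDistribution", "empirical_joint", "marginal", "conditional_mean"]


@dataclass
class JointDistribution:
    """Normalized probabilities over an integer (x2, x3) grid.

    prob[i, j] = P(x2 = x2_values[i], x3 = x3_values[j]).
    ``n_source_samples`` is 0 for exact (oracle-derived) distributions.
    """

    x2_values: np.ndarray
    x3_values: np.ndarray
    prob: np.ndarray
    n_source_samples: int = 0
    counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.x2_values = np.asarray(self.x2_values, dtype=np.int64)
        self.x3_values = np.asarray(self.x3_values, dtype=np.int64)
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.shape != (len(self.x2_values), len(self.x3_values)):
            raise ValueError("prob shape does not match supports")
        if np.any(self.prob < -1e-15):
            raise ValueError("probabilities must be non-negative")
        tot = self.prob.sum()
        if abs(tot - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1 (got {tot!r})")

    def p_x2(self) -> np.ndarray:
        return self.prob.sum(axis=1)

    def p_x3(self) -> np.ndarray:
        return self.prob.sum(axis=0)

    def mean(self, axis: str) -> float:
        if axis == "x2":
            return float(self.x2_values @ self.p_x2())
        return float(self.x3_values @ self.p_x3())

    def moments(self) -> dict:
        """First/second moments and the x2-x3 covariance."""
        p2, p3 = self.p_x2(), self.p_x3()
        m2, m3 = self.x2_values @ p2, self.x3_values @ p3
        v2 = (self.x2_values - m2) ** 2 @ p2
        v3 = (self.x3_values - m3) ** 2 @ p3
        cov = float(np.einsum("i,ij,j->", self.x2_values - m2, self.prob, self.x3_values - m3))
        return {"mean_x2": float(m2), "mean_x3": float(m3), "var_x2": float(v2),
                "var_x3": float(v3), "cov": cov}

    def sample(self, n: int, seed: int) -> SnapshotEnsemble:
        """Draw n independent (x2, x3) pairs from this distribution."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        flat = self.prob.ravel()
        flat = np.clip(flat, 0, None)
        flat = flat / flat.sum()
        idx = rng.choice(flat.size, size=n, p=flat)
        i2, i3 = np.unravel_index(idx, self.prob.shape)
        samples = np.column_stack([self.x2_values[i2], self.x3_values[i3]])
        return SnapshotEnsemble(samples=samples, meta={"seed": int(seed), "source": "resampled"})

    # -- I/O: 3-column TSV (x2, x3, count-or-probability) ----------------

    def to_tsv(self, path) -> None:
        kind = "count" if self.counts is not None else "probability"
        mat = self.counts if self.counts is not None else self.prob
        i2, i3 = np.nonzero(mat)
        df = pd.DataFrame(
            {"x2": self.x2_values[i2], "x3": self.x3_values[i3], kind: mat[i2, i3]}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "JointDistribution":
        df = pd.read_csv(path, sep="\t")
        value_col = "count" if "count" in df.columns else "probability"
        x2 = df["x2"].to_numpy(dtype=np.int64)
        x3 = df["x3"].to_numpy(dtype=np.int64)
        vals = df[value_col].to_numpy(dtype=float)
        x2_values = np.arange(x2.min(), x2.max() + 1)
        x3_values = np.arange(x3.min(), x3.max() + 1)
        mat = np.zeros((len(x2_values), len(x3_values)))
        mat[x2 - x2.min(), x3 - x3.min()] = vals
        if value_col == "count":
            n = int(round(mat.sum()))
            return cls(x2_values, x3_values, mat / mat.sum(), n_source_samples=n, counts=mat)
        return cls(x2_values, x3_values, mat / mat.sum())


def empirical_joint(samples: SnapshotEnsemble) -> JointDistribution:
    """Histogram an ensemble into a JointDistribution (probabilities = counts/N)."""
    x2, x3 = samples.x2, samples.x3
    x2_values = np.arange(x2.min(), x2.max() + 1)
    x3_values = np.arange(x3.min(), x3.max() + 1)
    counts = np.zeros((len(x2_values), len(x3_values)))
    np.add.at(counts, (x2 - x2.min(), x3 - x3.min()), 1.0)
    return JointDistribution(
        x2_values, x3_values, counts / samples.n, n_source_samples=samples.n, counts=counts
    )


def marginal(joint: JointDistribution, axis: str) -> np.ndarray:
    """Marginal probability vector over ``axis`` ('x2' or 'x3')."""
    if axis == "x2":
        return joint.p_x2()
    if axis == "x3":
        return joint.p_x3()
    raise ValueError("axis must be 'x2' or 'x3'")


def conditional_mean(samples_or_joint, of: str = "x3", given: str = "x2"):
    """Table of conditional averages <of | given>.

    Returns ``(values, means)`` restricted to conditioning states with at
    least one observation (nothing is imputed for unseen states).  This is
    the naive rate read-out that is only valid when the conditioning
    variable fluctuates slowly.
    """
    if of == given or {of, given} != {"x2", "x3"}:
        raise ValueError("of/given must be 'x2' and 'x3' in some order")
    if isinstance(samples_or_joint, SnapshotEnsemble):
        joint = empirical_joint(samples_or_joint)
    else:
        joint = samples_or_joint
    if given == "x2":
        cond_vals, weights, target = joint.x2_values, joint.prob, joint.x3_values
    else:
        cond_vals, weights, target = joint.x3_values, joint.prob.T, joint.x2_values
    mass = weights.sum(axis=1)
    keep = mass > 0
    means = (weights[keep] @ target.astype(float)) / mass[keep]
    return cond_vals[keep], means
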