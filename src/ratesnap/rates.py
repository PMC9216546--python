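"""Rate laws (propensity functions) for discrete-state reaction networks.

Every rate law used by the built-in example systems is one of a small
parametric family -- constant, linear, Hill, Hill plus a linear or constant
term, and mass-action dimerization.  Keeping the family parametric (rather
than accepting arbitrary callables in the hot path) lets the stochastic
simulator compile a single fast kernel; arbitrary callables are still
accepted by the slow reference paths.

The Hill law is

    f(x) = lam * x**n / (K**n + x**n)

with ``n > 0`` activation, ``n < 0`` repression (algebraically rewritten as
``lam * K**|n| / (K**|n| + x**|n|)`` so the value at ``x = 0`` is the
repressor-absent limit ``lam``), and ``n = 0`` defined as the shared limit
``lam / 2`` of both branches so parameter sweeps crossing zero cooperativity
stay continuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HillParams",
    "hill_value",
    "hill_rate",
    "Constant",
    "Linear",
    "Hill",
    "HillPlusLinear",
    "HillPlusConstant",
    "MassActionDimer",
    "KIND_CODES",
]

# integer codes shared with the compiled SSA kernel
KIND_CODES = {
    "constant": 0,
    "linear": 1,
    "hill": 2,
    "hill_plus_linear": 3,
    "hill_plus_constant": 4,
    "mass_action_dimer": 5,
}


@dataclass(frozen=True)
class HillParams:
    """Parameters of a Hill rate law.

    lam : maximal rate (molecules per unit time), >= 0.
    n   : Hill coefficient; may be negative (repression) or zero.
    K   : half-maximal abundance (molecules), > 0.
    """

    lam: float
    n: float
    K: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"Hill K must be > 0, got {self.K}")
        if self.lam < 0:
            raise ValueError(f"Hill lam must be >= 0, got {self.lam}")


def hill_value(x, lam: float, n: float, K: float):
    """Evaluate the Hill law elementwise on non-negative ``x``.

    Vectorized; returns a float array of the broadcast shape of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if n > 0:
        xn = np.where(x > 0, x, 1.0) ** n
        out = np.where(x > 0, lam * xn / (K**n + xn), 0.0)
    elif n < 0:
        m = -n
        out = lam * K**m / (K**m + x**m)  # x=0 -> lam exactly
    else:
        out = np.full_like(x, 0.5 * lam)
    return out if out.shape else float(out)


def hill_rate(params: HillParams):
    """Return the Hill rate as a vectorized function of one abundance."""

    def f(x):
        return hill_value(x, params.lam, params.n, params.K)

    f.params = params
    return f


class _RateLaw:
    """Base class: a propensity over full state vectors.

    ``__call__`` accepts a state array whose last axis indexes species and
    returns the rate with that axis dropped, so the same object serves the
    scalar SSA path and vectorized grid evaluation in the CME oracle.
    """

    kind: str

    def __call__(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def encode(self) -> tuple[int, int, int, float, float, float, float]:
        """(kind, sA, sB, p0, p1, p2, p3) row for the compiled kernel."""
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class Constant(_RateLaw):
    value: float
    kind = "constant"

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("constant rate must be >= 0")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape[:-1], self.value)
        return out if out.shape else float(out)

    def encode(self):
        return (0, -1, -1, self.value, 0.0, 0.0, 0.0)

    def to_dict(self):
        return {"kind": self.kind, "value": self.value}


@dataclass(frozen=True)
class Linear(_RateLaw):
    """``coef * x[species]`` -- e.g. first-order degradation with coef=1/tau."""

    coef: float
    species: int
    kind = "linear"

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.coef * x[..., self.species]

    def encode(self):
        return (1, self.species, -1, self.coef, 0.0, 0.0, 0.0)

    def to_dict(self):
        return {"kind": self.kind, "coef": self.coef, "species": self.species}


@dataclass(frozen=True)
class Hill(_RateLaw):
    params: HillParams
    species: int
    kind = "hill"

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return hill_value(x[..., self.species], self.params.lam, self.params.n, self.params.K)

    def encode(self):
        p = self.params
        return (2, self.species, -1, p.lam, p.n, p.K, 0.0)

    def to_dict(self):
        p = self.params
        return {"kind": self.kind, "lam": p.lam, "n": p.n, "K": p.K, "species": self.species}


@dataclass(frozen=True)
class HillPlusLinear(_RateLaw):
    """Hill term on one species plus ``c * x[other]`` (e.g. basal drive)."""

    params: HillParams
    species: int
    c: float
    other: int
    kind = "hill_plus_linear"

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        h = hill_value(x[..., self.species], self.params.lam, self.params.n, self.params.K)
        return h + self.c * x[..., self.other]

    def encode(self):
        p = self.params
        return (3, self.species, self.other, p.lam, p.n, p.K, self.c)

    def to_dict(self):
        p = self.params
        return {
            "kind": self.kind,
            "lam": p.lam,
            "n": p.n,
            "K": p.K,
            "species": self.species,
            "c": self.c,
            "other": self.other,
        }


@dataclass(frozen=True)
class HillPlusConstant(_RateLaw):
    params: HillParams
    species: int
    c: float
    kind = "hill_plus_constant"

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        h = hill_value(x[..., self.species], self.params.lam, self.params.n, self.params.K)
        return h + self.c

    def encode(self):
        p = self.params
        return (4, self.species, -1, p.lam, p.n, p.K, self.c)

    def to_dict(self):
        p = self.params
        return {
            "kind": self.kind,
            "lam": p.lam,
            "n": p.n,
            "K": p.K,
            "species": self.species,
            "c": self.c,
        }


@dataclass(frozen=True)
class MassActionDimer(_RateLaw):
    """``gamma * x * (x - 1)``; vanishes for x < 2 so a 2-molecule removal
    can never drive the count negative."""

    gamma: float
    species: int
    kind = "mass_action_dimer"

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        v = x[..., self.species]
        return self.gamma * v * (v - 1.0)

    def encode(self):
        return (5, self.species, -1, self.gamma, 0.0, 0.0, 0.0)

    def to_dict(self):
        return {"kind": self.kind, "gamma": self.gamma, "species": self.species}


_LAW_CLASSES = {
    "constant": Constant,
    "linear": Linear,
    "hill": Hill,
    "hill_plus_linear": HillPlusLinear,
    "hill_plus_constant": HillPlusConstant,
    "mass_action_dimer": MassActionDimer,
}


def rate_law_from_dict(d: dict) -> _RateLaw:
    """Inverse of ``to_dict`` for every built-in rate-law kind."""
    d = dict(d)
    kind = d.pop("kind")
    if kind not in _LAW_CLASSES:
        raise ValueError(f"unknown rate-law kind {kind!r}; known: {sorted(_LAW_CLASSES)}")
    if kind in ("hill", "hill_plus_linear", "hill_plus_constant"):
        params = HillParams(lam=d.pop("lam"), n=d.pop("n"), K=d.pop("K"))
        return _LAW_CLASSES[kind](params=params, **d)
    return _LAW_CLASSES[kind](**d)
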