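"""Reaction networks and the built-in three-component example motifs.

All built-in systems share one conserved pair of reactions for the species
of interest X3,

    x3 --f(x2)-->  x3 + 1        f(x2) = lam * x2**n / (K**n + x2**n)
    x3 --x3/tau3-> x3 - 1        (or dimeric: rate gamma*x3*(x3-1), -2)

embedded in four different upstream X1, X2 feedback architectures that
produce bistable, oscillating, noise-controlling, and noise-enhancing
global dynamics.  The inference machinery only ever sees snapshots of
(x2, x3); the upstream dynamics exist to generate realistically diverse
joint distributions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

from .rates import (
    Constant,
    Hill,
    HillParams,
    HillPlusConstant,
    HillPlusLinear,
    Linear,
    MassActionDimer,
    rate_law_from_dict,
)

__all__ = [
    "Reaction",
    "ReactionSystem",
    "DegradationSpec",
    "build_example_system",
    "EXAMPLE_SYSTEMS",
]


@dataclass(frozen=True)
class Reaction:
    """A single reaction channel: state jump ``d`` fired at rate ``propensity(x)``."""

    stoich_change: tuple[int, ...]
    propensity: Callable

    def __post_init__(self):
        object.__setattr__(self, "stoich_change", tuple(int(d) for d in self.stoich_change))


@dataclass
class ReactionSystem:
    species_names: list[str]
    reactions: list[Reaction]
    observed_pair: tuple[int, int] = (1, 2)
    name: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        ns = len(self.species_names)
        for r in self.reactions:
            if len(r.stoich_change) != ns:
                raise ValueError(
                    f"stoichiometry length {len(r.stoich_change)} != {ns} species"
                )
        i, j = self.observed_pair
        if i == j or not (0 <= i < ns and 0 <= j < ns):
            raise ValueError(f"observed_pair {self.observed_pair} invalid for {ns} species")

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def propensities(self, x) -> np.ndarray:
        """All reaction rates at state(s) ``x`` (last axis = species)."""
        x = np.asarray(x, dtype=float)
        return np.stack([np.asarray(r.propensity(x), dtype=float) for r in self.reactions], axis=-1)

    def encode(self):
        """Compact arrays consumed by the compiled SSA kernel."""
        rows = np.array([r.propensity.encode() for r in self.reactions], dtype=np.float64)
        stoich = np.array([r.stoich_change for r in self.reactions], dtype=np.int64)
        return rows, stoich

    # -- plain-text config round trip ------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": list(self.species_names),
            "observed_pair": list(self.observed_pair),
            "params": dict(self.params),
            "reactions": [
                {"stoich": list(r.stoich_change), "rate": r.propensity.to_dict()}
                for r in self.reactions
            ],
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionSystem":
        reactions = [
            Reaction(tuple(r["stoich"]), rate_law_from_dict(r["rate"])) for r in d["reactions"]
        ]
        return cls(
            species_names=list(d["species"]),
            reactions=reactions,
            observed_pair=tuple(d.get("observed_pair", (1, 2))),
            name=d.get("name", ""),
            params=dict(d.get("params", {})),
        )

    @classmethod
    def from_yaml(cls, path_or_text) -> "ReactionSystem":
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = path_or_text
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class DegradationSpec:
    """Degradation channel of the observed downstream species.

    step        : molecules removed per event (1 linear, 2 dimeric).
    propensity  : g(x3) >= 0, vectorized, with g(x) = 0 for x < step.
    scale_known : False means the overall scale (1/tau3 or gamma) is not
                  known to the analyst, in which case inferred rates carry
                  an unknown global factor (tau3*f instead of f).
    """

    step: int
    propensity: Callable
    scale_known: bool = True
    label: str = "linear"

    def __post_init__(self):
        if self.step < 1:
            raise ValueError("degradation step must be a positive integer")

    @classmethod
    def linear(cls, tau3: float = 1.0, scale_known: bool = True) -> "DegradationSpec":
        if tau3 <= 0:
            raise ValueError("tau3 must be > 0")

        def g(x):
            return np.asarray(x, dtype=float) / tau3

        g.tau3 = tau3
        return cls(step=1, propensity=g, scale_known=scale_known, label="linear")

    @classmethod
    def dimeric(cls, gamma: float = 2.0, scale_known: bool = True) -> "DegradationSpec":
        if gamma <= 0:
            raise ValueError("gamma must be > 0")

        def g(x):
            x = np.asarray(x, dtype=float)
            return gamma * x * (x - 1.0)

        g.gamma = gamma
        return cls(step=2, propensity=g, scale_known=scale_known, label="dimeric")


# ---------------------------------------------------------------------------
# built-in example systems
# ---------------------------------------------------------------------------

EXAMPLE_SYSTEMS = ("bistable", "oscillating", "noise_controlling", "noise_enhancing")

# Defaults for each motif.  The conserved X3 part is shared: Hill production
# f(x2) with (lam3, n3, K3) and linear decay 1/tau3 (or gamma-dimeric).
_DEFAULTS: dict[str, dict] = {
    "common": dict(lam3=80.0, n3=2.0, K3=40.0, tau3=1.0, gamma=2.0),
    "bistable": dict(lam=50.0, n=6.0, K=37.0, c=15.0, tau1=1.0, tau2=1.0),
    "oscillating": dict(
        lam1=50000.0, n1=10.0, K1=0.1, lam2=80.0, n2=1.0, K2=100.0, tau1=1.0, tau2=1.0
    ),
    "noise_controlling": dict(lam1=50.0, lam2=3000.0, n2=10.0, K2=10.0, tau1=50.0, tau2=1.0),
    "noise_enhancing": dict(lam=25.0, n=4.0, K=50.0, c=8.0, f1=5.0, tau1=1.0, tau2=1.0),
}


def build_example_system(
    name: str,
    degradation: str = "linear",
    overrides: dict | None = None,
) -> ReactionSystem:
    """Construct one of the built-in three-component motifs.

    Parameters
    ----------
    name : one of ``bistable``, ``oscillating``, ``noise_controlling``,
        ``noise_enhancing``.
    degradation : ``linear`` (rate x3/tau3, removes 1) or ``dimeric``
        (rate gamma*x3*(x3-1), removes 2).
    overrides : optional map of declared parameters.  Besides the motif's
        own parameters this accepts the conserved-part parameters
        ``lam3, n3, K3, tau3, gamma`` and the lifetimes ``tau1, tau2``.
        At the default lifetimes every birth law is exactly the printed
        one; overriding ``tau1``/``tau2`` multiplies the corresponding
        birth law by ``tau_default / tau`` so the fluctuation time-scale
        moves while the stationary means (the deterministic fixed point)
        stay put.

    Returns a :class:`ReactionSystem` with species ``["x1", "x2", "x3"]``
    and ``observed_pair=(1, 2)``.
    """
    if name not in EXAMPLE_SYSTEMS:
        raise ValueError(f"unknown system {name!r}; valid names: {EXAMPLE_SYSTEMS}")
    if degradation not in ("linear", "dimeric"):
        raise ValueError(f"degradation must be 'linear' or 'dimeric', got {degradation!r}")

    p = copy.deepcopy(_DEFAULTS["common"])
    p.update(copy.deepcopy(_DEFAULTS[name]))
    if overrides:
        unknown = set(overrides) - set(p)
        if unknown:
            raise ValueError(f"unknown override(s) {sorted(unknown)}; declared: {sorted(p)}")
        p.update(overrides)

    tau1, tau2, tau3 = p.get("tau1", 1.0), p.get("tau2", 1.0), p["tau3"]
    if min(tau1, tau2, tau3) <= 0:
        raise ValueError("lifetimes must be > 0")
    # time-scale changes are expressed relative to the motif's printed
    # lifetimes: at the defaults the birth laws are exactly as printed
    rel_tau1 = tau1 / _DEFAULTS[name].get("tau1", 1.0)
    rel_tau2 = tau2 / _DEFAULTS[name].get("tau2", 1.0)

    def scaled(law, tau):
        # birth propensity f_i(x)/tau_rel: keeps the rate-balance fixed
        # point while tau_i sets the relaxation time-scale
        if tau == 1.0:
            return law
        if isinstance(law, Constant):
            return Constant(law.value / tau)
        if isinstance(law, Hill):
            q = law.params
            return Hill(HillParams(q.lam / tau, q.n, q.K), law.species)
        if isinstance(law, HillPlusLinear):
            q = law.params
            return HillPlusLinear(HillParams(q.lam / tau, q.n, q.K), law.species, law.c / tau, law.other)
        if isinstance(law, HillPlusConstant):
            q = law.params
            return HillPlusConstant(HillParams(q.lam / tau, q.n, q.K), law.species, law.c / tau)
        if isinstance(law, Linear):
            return Linear(law.coef / tau, law.species)
        raise TypeError(f"cannot scale {law!r}")

    # upstream birth laws per motif (species indices: x1=0, x2=1, x3=2)
    if name == "bistable":
        f1 = HillPlusConstant(HillParams(p["lam"], p["n"], p["K"]), species=1, c=p["c"])
        f2 = Linear(1.0, species=0)
    elif name == "oscillating":
        f1 = Hill(HillParams(p["lam1"], -p["n1"], p["K1"]), species=2)
        f2 = Hill(HillParams(p["lam2"], p["n2"], p["K2"]), species=0)
    elif name == "noise_controlling":
        f1 = Linear(p["lam1"], species=2)
        f2 = Hill(HillParams(p["lam2"], -p["n2"], p["K2"]), species=0)
    else:  # noise_enhancing
        f1 = Constant(p["f1"])
        f2 = HillPlusLinear(HillParams(p["lam"], p["n"], p["K"]), species=2, c=p["c"], other=0)

    f3 = Hill(HillParams(p["lam3"], p["n3"], p["K3"]), species=1)

    reactions = [
        Reaction((+1, 0, 0), scaled(f1, rel_tau1)),
        Reaction((-1, 0, 0), Linear(1.0 / tau1, species=0)),
        Reaction((0, +1, 0), scaled(f2, rel_tau2)),
        Reaction((0, -1, 0), Linear(1.0 / tau2, species=1)),
        Reaction((0, 0, +1), f3),
    ]
    if degradation == "linear":
        reactions.append(Reaction((0, 0, -1), Linear(1.0 / tau3, species=2)))
    else:
        reactions.append(Reaction((0, 0, -2), MassActionDimer(p["gamma"], species=2)))

    p["degradation"] = degradation
    return ReactionSystem(
        species_names=["x1", "x2", "x3"],
        reactions=reactions,
        observed_pair=(1, 2),
        name=name,
        params=p,
    )


def degradation_spec_for(system: ReactionSystem, scale_known: bool = True) -> DegradationSpec:
    """The DegradationSpec matching a built-in system's X3 death channel."""
    p = system.params
    if p.get("degradation", "linear") == "dimeric":
        return DegradationSpec.dimeric(gamma=p["gamma"], scale_known=scale_known)
    return DegradationSpec.linear(tau3=p["tau3"], scale_known=scale_known)


def true_rate_function(system: ReactionSystem):
    """The conserved X3 production rate f(x2) of a built-in system."""
    p = system.params
    from .rates import hill_rate

    return hill_rate(HillParams(p["lam3"], p["n3"], p["K3"]))
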