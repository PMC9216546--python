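"""Shared fixtures: small exactly-solvable systems and their oracles.

Everything here is generated at test time; session scope keeps the cost of
the sparse oracle solves and SSA warm-up to one payment per run.
"""

import numpy as np
import pytest

import ratesnap as rs
from ratesnap.rates import Constant, Linear
from ratesnap.reactions import Reaction, ReactionSystem

# scaled-down noise-enhancing parameters: same topology, means ~18,
# exactly solvable in a small truncated box
REDUCED = dict(lam3=32.0, K3=16.0, f1=2.0, lam=12.0, K=12.0, c=4.0)
REDUCED_BOUNDS = (13, 60, 56)


def make_poisson_system(lam: float = 5.0, tau: float = 1.0) -> ReactionSystem:
    """Constant-production / linear-degradation birth-death pair.

    x2 is pinned at 0 (degenerate regulator) so the observed pair matches
    the package convention; x3 is Poisson(lam*tau) at stationarity.
    """
    return ReactionSystem(
        species_names=["x2", "x3"],
        reactions=[
            Reaction((0, +1), Constant(lam)),
            Reaction((0, -1), Linear(1.0 / tau, species=1)),
        ],
        observed_pair=(0, 1),
        name="poisson_birth_death",
    )


@pytest.fixture(scope="session")
def poisson_system():
    return make_poisson_system()


@pytest.fixture(scope="session")
def poisson_oracle(poisson_system):
    return rs.solve_stationary(poisson_system, bounds=(0, 60))


@pytest.fixture(scope="session")
def reduced_system():
    return rs.build_example_system("noise_enhancing", overrides=REDUCED)


@pytest.fixture(scope="session")
def reduced_oracle(reduced_system):
    dist = rs.solve_stationary(reduced_system, bounds=REDUCED_BOUNDS)
    assert dist.leaked_mass < 1e-6
    return dist


@pytest.fixture(scope="session")
def reduced_joint(reduced_oracle):
    return reduced_oracle.joint_observed((1, 2))


@pytest.fixture(scope="session")
def reduced_true_rate(reduced_system):
    return rs.true_rate_function(reduced_system)


@pytest.fixture(scope="session")
def linear_degradation():
    return rs.DegradationSpec.linear(tau3=1.0)


@pytest.fixture(scope="session")
def reduced_ensemble(reduced_joint):
    """50k i.i.d. draws from the exact reduced-system joint."""
    return reduced_joint.sample(50_000, seed=20250917)


def uniform_joint():
    return rs.JointDistribution(
        x2_values=np.array([1, 2]),
        x3_values=np.array([3, 4]),
        prob=np.full((2, 2), 0.25),
    )
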