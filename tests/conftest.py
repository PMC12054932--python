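"""Shared fixtures: the eleven matched-effort validation scenarios.

Each scenario fixes the true specimen totals on the study area (30 000
targets; markers varied to set the common-to-rare ratio), the pre-set
linear target count x, and the published optimal field-of-view
allocation at the matched effort budget (omega = 2, density 27).
"""

from dataclasses import dataclass

import pytest


@dataclass(frozen=True)
class Scenario:
    u: float
    x_stop: int
    n3c: int
    n3e: int
    critical_density: float  # printed to 4 significant figures (inf at u=1)


SCENARIOS = [
    Scenario(1.0, 482, 17, 17, float("inf")),
    Scenario(1.2, 524, 17, 20, 132.0),
    Scenario(1.5, 574, 17, 25, 29.95),
    Scenario(2.0, 635, 17, 33, 11.87),
    Scenario(3.0, 711, 17, 47, 5.687),
    Scenario(6.0, 806, 16, 83, 2.693),
    Scenario(10.0, 852, 15, 119, 1.803),
    Scenario(15.0, 877, 14, 154, 1.363),
    Scenario(20.0, 890, 14, 180, 1.132),
    Scenario(30.0, 903, 13, 219, 0.8821),
    Scenario(60.0, 917, 11, 283, 0.5888),
]

OMEGA = 2.0
DENSITY = 27.0
N_TARGETS = 30_000


@pytest.fixture(scope="session")
def scenarios() -> list[Scenario]:
    return SCENARIOS


def integer_allocation_search(dp, budget: float) -> tuple[float, tuple[int, int]]:
    """Brute-force oracle: minimise the two-term FOVS error over every
    integer (N3C, N3E) pair whose expected effort fits the budget.

    The error is strictly decreasing in N3E, so for each N3C the best
    affordable N3E is the largest one the remaining budget allows; the
    search over N3C is exhaustive.
    """
    import math

    from fovcount.design import error_fovs_two_dim

    cost_c = dp.omega + dp.density  # expected effort per calibration FOV
    cost_e = dp.omega + dp.density / dp.u_hat
    best_err, best_pair = math.inf, None
    for n3c in range(1, int(budget / cost_c) + 1):
        n3e = int((budget - cost_c * n3c) / cost_e)
        if n3e < 1:
            continue
        err = error_fovs_two_dim(dp, n3c, n3e)
        if err < best_err:
            best_err, best_pair = err, (n3c, n3e)
    return best_err, best_pair
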