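"""Closed-form sampling-design calculus for the two count methods.

Everything here is expressed in terms of a :class:`DesignPoint`: the
target-to-marker ratio ``u`` (>= 1 by convention; use
:func:`reversed_role` when markers outnumber targets), the mean density
of the common specimen per field of view ``Y3x``, the field-of-view
transition effort factor ``omega`` and the marker-dose variance term
``T``.  From these four numbers the module computes

* error-versus-effort curves for both methods,
* the optimal split of a FOVS effort budget between calibration- and
  extrapolation-count fields of view (stationarity of the two-dimensional
  error surface),
* the critical density ``Y3x*`` above which the FOVS method is the more
  efficient choice, and
* the effort (or field-of-view counts) required to reach a target error.

The linear effort model is ``e_L = A x`` with per-specimen effort
coefficient ``A = omega / Y3x + 1 + 1/u``; the FOVS effort model charges
``omega`` per field of view plus one unit per specimen.  Both error
curves decay as ``1 / sqrt(effort)`` towards the dose-error floor
``100 sqrt(T)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "DesignPoint",
    "OptimalAllocation",
    "Method",
    "MethodChoice",
    "effort_coefficient",
    "error_vs_effort_linear",
    "error_fovs_two_dim",
    "n3e_from_effort",
    "optimal_allocation",
    "error_vs_effort_fovs",
    "error_ratio",
    "critical_density",
    "choose_method",
    "effort_for_error_linear",
    "allocation_for_error",
    "effort_for_error_fovs",
    "effort_difference",
    "reversed_role",
    "round_half_away",
]


class Method(str, Enum):
    linear = "linear"
    fovs = "fovs"
    equivalent = "equivalent"


@dataclass(frozen=True)
class DesignPoint:
    """Assemblage/observer parameters driving all planning formulas.

    ``u_hat`` is the common-to-rare ratio estimate (``x/n`` for the linear
    method, ``Y3x/Y3n`` for the FOVS method); ``density`` is the mean
    number of common specimens per field of view (``Y3x``).
    """

    u_hat: float
    density: float
    omega: float = 2.0
    dose_error: float = 0.0

    def __post_init__(self) -> None:
        if self.u_hat <= 0:
            raise ValueError("u_hat must be > 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.dose_error < 0:
            raise ValueError("dose_error must be >= 0")

    def _require_primal(self) -> None:
        if self.u_hat < 1:
            raise ValueError(
                "u_hat < 1: markers are more common than targets; "
                "use reversed_role() and read densities against the markers"
            )


@dataclass(frozen=True)
class OptimalAllocation:
    """Optimal numbers of calibration (N3C*) and extrapolation (N3E*)
    fields of view, continuous and rounded, for a FOVS effort budget."""

    n3c_star: float
    n3e_star: float
    n3c: int
    n3e: int
    delta_star: float
    effort: float


@dataclass(frozen=True)
class MethodChoice:
    critical_density: float
    recommended: Method
    error_ratio: float


def round_half_away(value: float, minimum: int = 1) -> int:
    """Round to the nearest integer, halves away from zero, floored at
    ``minimum`` (a planned field-of-view count of zero is meaningless)."""
    return max(int(math.floor(value + 0.5)), minimum)


def effort_coefficient(dp: DesignPoint) -> float:
    """Per-specimen effort of the linear method, ``A = omega/Y3x + 1 + 1/u``.

    ``e_L = A x`` once the expected marker count ``n = x / u`` and the
    expected field-of-view transits ``x / Y3x`` are substituted into the
    linear effort model.
    """
    return dp.omega / dp.density + 1.0 + 1.0 / dp.u_hat


def error_vs_effort_linear(dp: DesignPoint, effort: float) -> float:
    """Linear-method error (percent) at a given effort:
    ``sigma_L(e) = 100 sqrt(T + (1 + u) A / e)``."""
    dp._require_primal()
    if effort <= 0:
        raise ValueError("effort must be > 0")
    a = effort_coefficient(dp)
    return 100.0 * math.sqrt(dp.dose_error + (1.0 + dp.u_hat) * a / effort)


def error_fovs_two_dim(dp: DesignPoint, n3c: float, n3e: float) -> float:
    """FOVS error (percent) for explicit field-of-view counts:
    ``sigma_F(N3C, N3E) = 100 sqrt(T + 1/(N3C Y3x) + u/(N3E Y3x))``.

    The calibration term uses the Poisson approximation for the common
    specimen; the rare-count term is Poisson with expected count
    ``N3E Y3x / u``.
    """
    dp._require_primal()
    if n3c <= 0 or n3e <= 0:
        raise ValueError("field-of-view counts must be > 0")
    y = dp.density
    return 100.0 * math.sqrt(
        dp.dose_error + 1.0 / (n3c * y) + dp.u_hat / (n3e * y)
    )


def n3e_from_effort(dp: DesignPoint, effort: float, n3c: float) -> float:
    """Extrapolation fields of view affordable after ``n3c`` calibration
    fields: ``N3E = (e_F - (omega + Y3x) N3C) / (omega + Y3x / u)``.

    Substituting the expected specimen counts back into the FOVS effort
    model recovers ``e_F`` exactly (effort conservation).
    """
    dp._require_primal()
    remaining = effort - (dp.omega + dp.density) * n3c
    if remaining <= 0:
        raise ValueError(
            "calibration exhausts budget: effort must exceed "
            f"(omega + Y3x) * N3C = {(dp.omega + dp.density) * n3c:.6g}"
        )
    return remaining / (dp.omega + dp.density / dp.u_hat)


def _stationary_counts(dp: DesignPoint, effort: float) -> tuple[float, float, float]:
    """Continuous stationary point of the constrained FOVS error surface."""
    a1 = dp.omega + dp.density            # effort per calibration FOV
    a2 = dp.omega * dp.u_hat + dp.density
    s = math.sqrt(a1 * a2)
    n3c = effort / (a1 + s)
    n3e = effort * dp.u_hat / (a2 + s)
    delta = dp.u_hat * math.sqrt(a1 / a2)
    return n3c, n3e, delta


def optimal_allocation(dp: DesignPoint, effort: float) -> OptimalAllocation:
    """Optimal split of a FOVS effort budget between the two count stages.

    Setting the derivative of the budget-constrained error to zero gives

        N3C* = e_F / (omega + Y3x + sqrt((omega + Y3x)(omega u + Y3x)))
        N3E* = e_F u / (omega u + Y3x + sqrt((omega + Y3x)(omega u + Y3x)))

    with optimal count ratio ``delta* = N3E*/N3C* = u sqrt((omega + Y3x) /
    (omega u + Y3x))`` (independent of the budget).  Planned counts are
    rounded half away from zero with a floor of 1.
    """
    dp._require_primal()
    if effort <= 0:
        raise ValueError("effort must be > 0")
    n3c, n3e, delta = _stationary_counts(dp, effort)
    if n3c < 0.5 or n3e < 0.5:
        a1 = dp.omega + dp.density
        a2 = dp.omega * dp.u_hat + dp.density
        s = math.sqrt(a1 * a2)
        min_effort = max(0.5 * (a1 + s), 0.5 * (a2 + s) / dp.u_hat)
        raise ValueError(
            "effort budget too small for at least one field of view per "
            f"stage; minimum feasible effort is about {min_effort:.3g}"
        )
    return OptimalAllocation(
        n3c_star=n3c,
        n3e_star=n3e,
        n3c=round_half_away(n3c),
        n3e=round_half_away(n3e),
        delta_star=delta,
        effort=effort,
    )


def error_vs_effort_fovs(dp: DesignPoint, effort: float) -> float:
    """FOVS error (percent) at a given effort, at the optimal allocation:

        sigma_F(e) = 100 sqrt(T + [omega(1+u) + 2 Y3x
                     + 2 sqrt((Y3x+omega)(Y3x+u omega))] / (e Y3x)).
    """
    dp._require_primal()
    if effort <= 0:
        raise ValueError("effort must be > 0")
    y, w, u = dp.density, dp.omega, dp.u_hat
    num = w * (1.0 + u) + 2.0 * y + 2.0 * math.sqrt((y + w) * (y + u * w))
    return 100.0 * math.sqrt(dp.dose_error + num / (effort * y))


def error_ratio(dp: DesignPoint, effort: float) -> float:
    """Ratio ``sigma_L / sigma_F`` at equal effort (FOVS at its optimal
    allocation).  Values above 1 favour the FOVS method.  The ratio equals
    1 exactly at ``Y3x = Y3x*`` whatever the effort or dose error."""
    dp._require_primal()
    if effort <= 0:
        raise ValueError("effort must be > 0")
    y, w, u = dp.density, dp.omega, dp.u_hat
    te = dp.dose_error * effort
    num = w * (u + 1.0) + (2.0 + te + u) * y + y / u
    den = w * (u + 1.0) + (2.0 + te) * y + 2.0 * math.sqrt((y + w) * (y + u * w))
    return math.sqrt(num / den)


def critical_density(u_hat: float, omega: float) -> float:
    """Critical common-specimen density ``Y3x*`` above which the FOVS
    method is the more efficient choice:

        Y3x* = 2 omega (u**2 + sqrt(u**3 (1 + u(u-1)))) / ((u+1)(u-1)**2).

    This is the positive root of the quadratic dividing line
    ``(u**2-1)**2 Y**2 - 4 omega u**2 (1+u) Y - 4 omega**2 u**3 = 0``.
    At ``u = 1`` the dividing line recedes to infinity: the linear method
    is then always (marginally) superior.
    """
    if u_hat <= 0:
        raise ValueError("u_hat must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if u_hat == 1.0:
        return math.inf
    u = u_hat
    num = 2.0 * omega * (u**2 + math.sqrt(u**3 * (1.0 + u * (u - 1.0))))
    return num / ((u + 1.0) * (u - 1.0) ** 2)


def choose_method(
    dp: DesignPoint, effort: float | None = None, rel_tol: float = 1e-9
) -> MethodChoice:
    """Method-determination test: recommend the FOVS method iff the
    observed density exceeds the critical density ``Y3x*``.

    Ties (within ``rel_tol``) are reported as ``equivalent`` and resolved
    in favour of the linear method, which needs no extra conditions (no
    marker contrast or matched count regions).  ``effort`` only affects
    the reported error ratio when the dose error is non-zero; by default
    the pure count-error ratio (``T e = 0``) is reported.
    """
    dp._require_primal()
    ystar = critical_density(dp.u_hat, dp.omega)
    if math.isinf(ystar):
        ratio = error_ratio(
            DesignPoint(dp.u_hat, dp.density, dp.omega, 0.0), effort or 1.0
        )
        return MethodChoice(ystar, Method.linear, ratio)
    if effort is None:
        ratio = error_ratio(DesignPoint(dp.u_hat, dp.density, dp.omega, 0.0), 1.0)
    else:
        ratio = error_ratio(dp, effort)
    if math.isclose(dp.density, ystar, rel_tol=rel_tol):
        return MethodChoice(ystar, Method.equivalent, ratio)
    recommended = Method.fovs if dp.density > ystar else Method.linear
    return MethodChoice(ystar, recommended, ratio)


def _check_reachable(dp: DesignPoint, sigma_bar: float) -> float:
    var = (sigma_bar / 100.0) ** 2 - dp.dose_error
    if var <= 0:
        raise ValueError(
            "target error unattainable: limited by marker-dose uncertainty "
            f"(floor is {100.0 * math.sqrt(dp.dose_error):.4g}%)"
        )
    return var


def effort_for_error_linear(dp: DesignPoint, sigma_bar: float) -> float:
    """Linear-method effort needed for a target error ``sigma_bar`` (%):

        e_L = [omega(1+u) + Y3x(2+u) + Y3x/u] / (Y3x ((sigma/100)**2 - T)).

    Exact inverse of :func:`error_vs_effort_linear`.
    """
    dp._require_primal()
    var = _check_reachable(dp, sigma_bar)
    y, w, u = dp.density, dp.omega, dp.u_hat
    return (w * (1.0 + u) + y * (2.0 + u) + y / u) / (y * var)


def allocation_for_error(dp: DesignPoint, sigma_bar: float) -> OptimalAllocation:
    """Field-of-view counts needed for a target FOVS error ``sigma_bar``:

        N3C* = (sqrt(Y3x+omega) + sqrt(Y3x+u omega))
               / (Y3x sqrt(Y3x+omega) ((sigma/100)**2 - T))

    and ``N3E* = delta* N3C*``.  Plugging the pair back into
    :func:`error_fovs_two_dim` returns ``sigma_bar`` exactly.
    """
    dp._require_primal()
    var = _check_reachable(dp, sigma_bar)
    y, w, u = dp.density, dp.omega, dp.u_hat
    r1 = math.sqrt(y + w)
    r2 = math.sqrt(y + u * w)
    n3c = (r1 + r2) / (y * r1 * var)
    n3e = u * (r1 + r2) / (y * r2 * var)
    delta = u * r1 / r2
    effort = (w + y) * n3c + (w + y / u) * n3e
    return OptimalAllocation(
        n3c_star=n3c,
        n3e_star=n3e,
        n3c=round_half_away(n3c),
        n3e=round_half_away(n3e),
        delta_star=delta,
        effort=effort,
    )


def effort_for_error_fovs(dp: DesignPoint, sigma_bar: float) -> float:
    """FOVS effort needed for a target error ``sigma_bar`` (%):

        e_F = [2 Y3x + omega(1+u) + 2 sqrt((Y3x+omega)(Y3x+u omega))]
              / (Y3x ((sigma/100)**2 - T)).

    Exact inverse of :func:`error_vs_effort_fovs`.
    """
    dp._require_primal()
    var = _check_reachable(dp, sigma_bar)
    y, w, u = dp.density, dp.omega, dp.u_hat
    num = 2.0 * y + w * (1.0 + u) + 2.0 * math.sqrt((y + w) * (y + u * w))
    return num / (y * var)


def effort_difference(dp: DesignPoint, sigma_bar: float) -> float:
    """Effort saved by the FOVS method at a target error:
    ``e_L(sigma) - e_F(sigma)``.  Positive values favour the FOVS method;
    the sign agrees with :func:`choose_method` for all valid inputs."""
    return effort_for_error_linear(dp, sigma_bar) - effort_for_error_fovs(
        dp, sigma_bar
    )


def reversed_role(dp: DesignPoint) -> DesignPoint:
    """Swap the roles of targets and markers in a design point.

    When markers outnumber targets (``u < 1``) the planning formulas are
    applied to the mirrored assemblage: common-to-rare ratio ``1/u`` and
    density read against the *markers* per field of view,
    ``Y3n = Y3x / u``.  Applying the swap twice is the identity.
    """
    return DesignPoint(
        u_hat=1.0 / dp.u_hat,
        density=dp.density / dp.u_hat,
        omega=dp.omega,
        dose_error=dp.dose_error,
    )
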