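"""Concentration, error and effort estimates for exotic-marker count data.

Two count methods are supported.  In the *linear* method targets (x) and
exotic markers (n) are tallied jointly in one contiguous window until a
pre-set count is reached; the target concentration follows from the
target-to-marker ratio and the known marker spike.  In the *field-of-view
subsampling* (FOVS) method the common specimen type is characterised by
per-field-of-view calibration counts (mean ``Y3`` and standard deviation
``s3``) and the rare type is counted over many additional extrapolation
fields of view; the common count is extrapolated as ``x_hat = Y3 * N3E``.

All standard errors are expressed in percent of the concentration.  Both
error models share the marker-dose variance term ``T = s1P**2 / N1`` and
Poisson count terms; the FOVS model replaces the Poisson term of the
common specimen by the empirical between-field variance of the
calibration counts (with the small-sample c4 correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "Role",
    "StopRule",
    "MarkerSpike",
    "SampleSpec",
    "LinearTally",
    "FovCalibration",
    "FovExtrapolation",
    "ConcentrationResult",
    "c4_factor",
    "calibration_stats",
    "concentration_linear",
    "error_linear",
    "effort_linear",
    "extrapolated_common_count",
    "concentration_fovs",
    "error_fovs",
    "effort_fovs",
    "estimate_linear",
    "estimate_fovs",
    "normal_ci",
]


class Role(str, Enum):
    """Which specimen type is the common one (subject of calibration counts)."""

    targets_common = "targets_common"
    markers_common = "markers_common"


class StopRule(str, Enum):
    """Pre-determined quantity that terminates a linear count."""

    fixed_targets = "fixed_targets"
    fixed_markers = "fixed_markers"


@dataclass(frozen=True)
class MarkerSpike:
    """Exotic-marker spike added to a sample.

    Parameters
    ----------
    n_doses : int
        Number of marker doses (e.g. *Lycopodium* tablets) added, ``N1``.
    mean_per_dose : float
        Mean number of markers per dose, ``Y1``.
    sd_per_dose : float, default 0
        Standard deviation of markers per dose, ``s1``.  Zero means the
        spike size is known exactly.

    The proportional dose SD ``s1P = s1 / Y1`` and the dose-error variance
    term ``T = s1P**2 / N1`` are derived attributes.
    """

    n_doses: int
    mean_per_dose: float
    sd_per_dose: float = 0.0

    def __post_init__(self) -> None:
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.mean_per_dose <= 0:
            raise ValueError("mean_per_dose must be > 0")
        if self.sd_per_dose < 0:
            raise ValueError("sd_per_dose must be >= 0")

    @property
    def prop_sd(self) -> float:
        """Proportional SD of markers per dose, ``s1P``."""
        return self.sd_per_dose / self.mean_per_dose

    @property
    def dose_error_term(self) -> float:
        """Dose-error variance contribution ``T = s1P**2 / N1``."""
        return self.prop_sd**2 / self.n_doses

    @property
    def total_markers(self) -> float:
        """Expected total markers added, ``N1 * Y1``."""
        return self.n_doses * self.mean_per_dose


@dataclass(frozen=True)
class SampleSpec:
    """Total sample size (mass, area or volume), ``V``."""

    total_size: float
    size_unit: str = "arbitrary"

    def __post_init__(self) -> None:
        if self.total_size <= 0:
            raise ValueError("total_size must be > 0")


@dataclass(frozen=True)
class LinearTally:
    """Joint sequential count from one linear window: targets ``x``, markers ``n``."""

    targets: int
    markers: int
    stop_rule: StopRule = StopRule.fixed_targets

    def __post_init__(self) -> None:
        if self.targets < 0 or self.markers < 0:
            raise ValueError("counts must be non-negative")
        if self.targets + self.markers < 1:
            raise ValueError("empty tally: at least one specimen required")


@dataclass(frozen=True)
class FovCalibration:
    """Per-field-of-view counts of the common specimen type.

    Derived statistics: ``n_fov`` (= N3C), the sample mean ``Y3``, the
    Bessel-corrected SD ``s3`` and the c4-corrected proportional SD
    ``s3P = s3 / (c4(N3C) * Y3)``.
    """

    per_fov_counts: tuple[int, ...]
    role: Role = Role.targets_common

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.per_fov_counts)
        object.__setattr__(self, "per_fov_counts", counts)
        if len(counts) < 2:
            raise ValueError("at least 2 calibration fields of view required")
        if any(c < 0 for c in counts):
            raise ValueError("negative per-FOV count")
        if sum(counts) == 0:
            raise ValueError("no common specimens observed in calibration counts")

    @property
    def n_fov(self) -> int:
        return len(self.per_fov_counts)

    @property
    def total_count(self) -> int:
        return int(sum(self.per_fov_counts))

    @property
    def mean_per_fov(self) -> float:
        return self.total_count / self.n_fov

    @property
    def sd_per_fov(self) -> float:
        return float(np.std(self.per_fov_counts, ddof=1))

    @property
    def prop_sd(self) -> float:
        """c4-corrected proportional SD, ``s3P``."""
        return self.sd_per_fov / (c4_factor(self.n_fov) * self.mean_per_fov)


@dataclass(frozen=True)
class FovExtrapolation:
    """Extrapolation-count stage: ``n_fov`` (= N3E) fields of view scanned
    for the rare specimen type, yielding ``rare_count`` specimens."""

    n_fov: int
    rare_count: int

    def __post_init__(self) -> None:
        if self.n_fov < 1:
            raise ValueError("n_fov must be >= 1")
        if self.rare_count < 0:
            raise ValueError("rare_count must be >= 0")


@dataclass(frozen=True)
class ConcentrationResult:
    """Concentration estimate with its percent standard error and effort."""

    concentration: float
    total_error_pct: float
    effort: float
    method: str
    role: Role = Role.targets_common
    extrapolated_common: float | None = None
    approx_ci: tuple[float, float] | None = None
    advisory: str | None = field(default=None, compare=False)


def c4_factor(n: int) -> float:
    """Small-sample correction ``c4(n)`` for the bias of the sample SD.

    Under a normal model ``E[s] = c4(n) * sigma`` with

        c4(n) = sqrt(2 / (n - 1)) * Gamma(n / 2) / Gamma((n - 1) / 2).

    Strictly increasing in ``n`` and tending to 1; dividing ``s`` by
    ``c4(n)`` therefore de-biases small-sample SD estimates.
    """
    n = int(n)
    if n < 2:
        raise ValueError("c4 correction requires n >= 2")
    # gammaln avoids overflow for large n
    return math.sqrt(2.0 / (n - 1)) * math.exp(
        special.gammaln(n / 2.0) - special.gammaln((n - 1) / 2.0)
    )


def calibration_stats(
    per_fov_counts: Sequence[int], role: Role = Role.targets_common
) -> FovCalibration:
    """Build a :class:`FovCalibration` from raw per-field-of-view counts."""
    return FovCalibration(per_fov_counts=tuple(per_fov_counts), role=role)


def concentration_linear(
    tally: LinearTally, spike: MarkerSpike, sample: SampleSpec
) -> float:
    """Linear-method concentration ``c = x * N1 * Y1 / (n * V)``."""
    if tally.markers == 0:
        raise ValueError("no markers counted: concentration unbounded")
    return (
        tally.targets * spike.total_markers / (tally.markers * sample.total_size)
    )


def error_linear(tally: LinearTally, spike: MarkerSpike) -> float:
    """Linear-method total standard error in percent.

    ``sigma_L = 100 * sqrt(T + 1/x + 1/n)`` where both count terms are the
    squared proportional Poisson SDs of the tallies and ``T`` is the
    marker-dose contribution.
    """
    if tally.targets < 1 or tally.markers < 1:
        raise ValueError("error undefined unless x >= 1 and n >= 1")
    return 100.0 * math.sqrt(
        spike.dose_error_term + 1.0 / tally.targets + 1.0 / tally.markers
    )


def effort_linear(
    tally: LinearTally,
    omega: float,
    mean_targets_per_fov: float,
    asym: float = 1.0,
) -> float:
    """Linear-method effort ``e_L = omega * x / Y3x + asym * x + n``.

    One effort unit per specimen identified plus ``omega`` units per
    field-of-view transition; the number of transitions is approximated by
    ``x / Y3x``.  ``asym`` is the optional effort asymmetry factor applied
    to target identifications (1 = targets and markers cost the same).
    """
    if mean_targets_per_fov <= 0:
        raise ValueError("mean_targets_per_fov must be > 0")
    if omega < 0 or asym < 1:
        raise ValueError("omega must be >= 0 and asym >= 1")
    return omega * tally.targets / mean_targets_per_fov + asym * tally.targets + tally.markers


def extrapolated_common_count(
    calib: FovCalibration, extrap: FovExtrapolation
) -> float:
    """Extrapolated common-specimen count ``x_hat = Y3 * N3E``."""
    return calib.mean_per_fov * extrap.n_fov


def concentration_fovs(
    calib: FovCalibration,
    extrap: FovExtrapolation,
    spike: MarkerSpike,
    sample: SampleSpec,
) -> float:
    """FOVS-method concentration.

    With targets common (role ``targets_common``) the extrapolated target
    count enters the numerator: ``c_Fx = x_hat * N1 * Y1 / (n * V)``.
    With markers common the roles swap: the extrapolated *marker* count
    ``n_hat = Y3n * N3E`` enters the denominator and the counted rare
    targets the numerator, ``c_Fn = x * N1 * Y1 / (n_hat * V)``.
    """
    if extrap.rare_count == 0 and calib.role is Role.targets_common:
        raise ValueError("no rare specimens counted: concentration unbounded")
    common_hat = extrapolated_common_count(calib, extrap)
    if calib.role is Role.targets_common:
        return common_hat * spike.total_markers / (extrap.rare_count * sample.total_size)
    # markers common: common_hat estimates the marker count of the scanned area
    if common_hat == 0:
        raise ValueError("no markers in calibration counts: concentration unbounded")
    return extrap.rare_count * spike.total_markers / (common_hat * sample.total_size)


def error_fovs(
    calib: FovCalibration, extrap: FovExtrapolation, spike: MarkerSpike
) -> float:
    """FOVS-method total standard error in percent.

    ``sigma_F = 100 * sqrt(T + s3P**2 / N3C + 1/n)``: the common specimen
    contributes the empirical between-field variance of the calibration
    mean (c4-corrected), the rare specimen a Poisson term.
    """
    if extrap.rare_count < 1:
        raise ValueError("error undefined with zero rare count")
    return 100.0 * math.sqrt(
        spike.dose_error_term
        + calib.prop_sd**2 / calib.n_fov
        + 1.0 / extrap.rare_count
    )


def effort_fovs(
    calib: FovCalibration,
    extrap: FovExtrapolation,
    omega: float,
    asym: float = 1.0,
) -> float:
    """FOVS-method effort ``e_F = omega*N3C + asym*x + omega*N3E + n``
    with ``x`` the total specimens identified during calibration."""
    if omega < 0 or asym < 1:
        raise ValueError("omega must be >= 0 and asym >= 1")
    return (
        omega * calib.n_fov
        + asym * calib.total_count
        + omega * extrap.n_fov
        + extrap.rare_count
    )


def normal_ci(
    concentration: float, total_error_pct: float, z: float = 1.959963984540054
) -> tuple[float, float]:
    """Normal-approximation interval ``c * (1 +/- z * sigma / 100)``.

    A simple symmetric interval from the delta-method standard error; the
    lower bound is floored at zero.
    """
    half = z * total_error_pct / 100.0 * concentration
    return (max(concentration - half, 0.0), concentration + half)


def estimate_linear(
    tally: LinearTally,
    spike: MarkerSpike,
    sample: SampleSpec,
    omega: float = 2.0,
    mean_targets_per_fov: float | None = None,
    asym: float = 1.0,
    z: float = 1.959963984540054,
) -> ConcentrationResult:
    """Full linear-method estimate (concentration, error, effort, CI)."""
    advisory = None
    if tally.targets == 0:
        conc = 0.0
        advisory = "zero targets counted: concentration estimate is 0"
        err = float("nan")
    else:
        conc = concentration_linear(tally, spike, sample)
        err = error_linear(tally, spike)
    effort = (
        effort_linear(tally, omega, mean_targets_per_fov, asym)
        if mean_targets_per_fov
        else float("nan")
    )
    ci = normal_ci(conc, err, z) if not math.isnan(err) else None
    return ConcentrationResult(
        concentration=conc,
        total_error_pct=err,
        effort=effort,
        method="linear",
        approx_ci=ci,
        advisory=advisory,
    )


def estimate_fovs(
    calib: FovCalibration,
    extrap: FovExtrapolation,
    spike: MarkerSpike,
    sample: SampleSpec,
    omega: float = 2.0,
    asym: float = 1.0,
    z: float = 1.959963984540054,
) -> ConcentrationResult:
    """Full FOVS-method estimate (concentration, error, effort, CI)."""
    conc = concentration_fovs(calib, extrap, spike, sample)
    err = error_fovs(calib, extrap, spike)
    effort = effort_fovs(calib, extrap, omega, asym)
    return ConcentrationResult(
        concentration=conc,
        total_error_pct=err,
        effort=effort,
        method="fovs",
        role=calib.role,
        extrapolated_common=extrapolated_common_count(calib, extrap),
        approx_ci=normal_ci(conc, err, z),
    )
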