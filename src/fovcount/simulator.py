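"""Monte Carlo simulation of virtual study areas for the two count methods.

A virtual study area is a unit square carrying a fixed number of targets
and of exotic markers, each scattered independently and uniformly at
random.  A square grid of ``grid_side x grid_side`` half-open cells plays
the role of the non-overlapping microscope fields of view (33 x 33 = 1089
by default).  Each replicate draws a fresh area and estimates the known
target total with

* the linear method — a horizontal window strip is swept left to right
  until a pre-set number of targets is encountered, and the markers that
  fell inside the window are counted; and
* the FOVS method — disjoint random calibration and extrapolation cell
  sets are counted, with the effort budget matched to the linear method
  and split optimally between the two stages.

Two sampling engines produce identically-distributed replicates:

``"area"``
    literal geometry: scatter every specimen, cut the window, count cells.
``"fast"`` (default)
    samples the sufficient statistics of that geometry directly — the
    per-cell target counts of the sampled cells are multinomial, the
    marker count of a region is binomial in its area, and the window
    length is the relevant uniform order statistic (a Beta variate).
    This is an exact distributional shortcut, not an approximation, and
    makes 1e5-replicate experiments a matter of seconds.

Because both estimators are ratios with a random marker count in the
denominator, the textbook formulas carry an O(1/n) upward bias.  The
simulator therefore also reports mean-unbiased variants using the
classical Chapman-style correction ``(x - 1) (K + 1) / (n + 1)``
(exactly unbiased for inverse-sampling and binomial denominators up to a
vanishing truncation term); summaries use the corrected values by
default so that accuracy checks are not confounded by ratio bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np

from .design import DesignPoint, OptimalAllocation, optimal_allocation
from .estimators import c4_factor

__all__ = [
    "SimConfig",
    "StudyArea",
    "ReplicateResult",
    "SimSummary",
    "ExperimentResult",
    "fpc_factor",
    "generate_study_area",
    "per_fov_counts",
    "linear_window_count",
    "fov_replicate",
    "run_experiment",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-area and experiment parameters.

    ``n_targets`` and ``n_markers`` are the exact specimen totals placed
    on the unit square; their ratio is the true common-to-rare ratio and
    must be >= 1 (targets common).  ``x_stop`` is the pre-set linear
    target count; if omitted it is derived from ``effort_budget`` through
    the linear effort coefficient.  ``dose_sd`` (markers per dose) feeds
    the dose-error term ``T``; the default 0 reproduces the exactly-known
    spike used in the validation experiments.  ``planning_density`` is
    the whole-grid mean target density used by the design formulas; by
    default the integer part of ``n_targets / grid_side**2`` (the kind of
    round figure a practitioner would quote from a calibration count).
    """

    n_targets: int = 30_000
    n_markers: int = 1_000
    x_stop: int | None = None
    effort_budget: float | None = None
    omega: float = 2.0
    n_doses: int = 1
    dose_sd: float = 0.0
    iterations: int = 10_000
    seed: int = 0
    grid_side: int = 33
    window_height_fovs: int = 1
    planning_density: float | None = None
    bias_correction: bool = True

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.n_markers < 1:
            raise ValueError("specimen totals must be positive")
        if self.n_targets < self.n_markers:
            raise ValueError(
                "targets must be at least as common as markers (swap the "
                "labels for marker-common scenarios)"
            )
        if self.x_stop is None and self.effort_budget is None:
            raise ValueError("either x_stop or effort_budget is required")
        if self.iterations < 1 or self.grid_side < 2:
            raise ValueError("iterations >= 1 and grid_side >= 2 required")
        if not (1 <= self.window_height_fovs <= self.grid_side):
            raise ValueError("window_height_fovs must be in [1, grid_side]")

    @property
    def u_true(self) -> float:
        return self.n_targets / self.n_markers

    @property
    def dose_error_term(self) -> float:
        mean_per_dose = self.n_markers / self.n_doses
        return (self.dose_sd / mean_per_dose) ** 2 / self.n_doses

    @property
    def n_cells(self) -> int:
        return self.grid_side**2

    def resolved_planning_density(self) -> float:
        if self.planning_density is not None:
            return self.planning_density
        mean = self.n_targets / self.n_cells
        return float(int(mean)) if mean >= 1.0 else mean

    def design_point(self) -> DesignPoint:
        return DesignPoint(
            u_hat=self.u_true,
            density=self.resolved_planning_density(),
            omega=self.omega,
            dose_error=self.dose_error_term,
        )


@dataclass(frozen=True)
class StudyArea:
    """Scatter of targets and markers on the unit square; coordinate
    arrays have shape (n, 2)."""

    target_coords: np.ndarray
    marker_coords: np.ndarray

    @property
    def n_targets(self) -> int:
        return self.target_coords.shape[0]

    @property
    def n_markers(self) -> int:
        return self.marker_coords.shape[0]


@dataclass(frozen=True)
class ReplicateResult:
    method: str
    c_hat: float                 # textbook ratio estimate (NaN when n = 0)
    c_hat_unbiased: float        # Chapman-corrected estimate
    sigma_hat_pct: float         # estimated total error (NaN when n = 0)
    effort: float
    x: int
    n: int
    n3c: int = 0
    n3e: int = 0


@dataclass(frozen=True)
class SimSummary:
    method: str
    mean_c: float
    mean_sigma_pct: float
    empirical_sigma_pct: float
    mean_effort: float
    n_replicates: int
    n_excluded: int
    zero_rare_rate: float


@dataclass(frozen=True)
class ExperimentResult:
    config: SimConfig
    x_stop: int
    effort_budget: float
    allocation: OptimalAllocation
    linear: SimSummary
    fovs: SimSummary
    true_concentration: float = field(default=0.0)


def fpc_factor(population_units: int, sampled_units: int) -> float:
    """Finite-population correction ``sqrt((N - n) / (N - 1))`` applied to
    the standard error of a mean of ``n`` units sampled without
    replacement from ``N``.  Equals 1 for a single unit and 0 for a
    census (a census mean has no sampling error)."""
    if sampled_units < 1 or population_units < 1:
        raise ValueError("unit counts must be >= 1")
    if sampled_units > population_units:
        raise ValueError("cannot sample more units than the population holds")
    if population_units == 1:
        return 0.0 if sampled_units == 1 else 1.0
    return math.sqrt(
        (population_units - sampled_units) / (population_units - 1.0)
    )


def _rng(cfg: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, *stream])


def generate_study_area(cfg: SimConfig, replicate_seed: int = 0) -> StudyArea:
    """Scatter exactly ``n_targets`` and ``n_markers`` uniform points on
    the unit square; deterministic in ``(cfg.seed, replicate_seed)``."""
    rng = _rng(cfg, 0, replicate_seed)
    return StudyArea(
        target_coords=rng.random((cfg.n_targets, 2)),
        marker_coords=rng.random((cfg.n_markers, 2)),
    )


def per_fov_counts(coords: np.ndarray, grid_side: int) -> np.ndarray:
    """Counts per half-open grid cell (row-major, length grid_side**2).

    Cells are ``[i/g, (i+1)/g) x [j/g, (j+1)/g)`` so every specimen
    belongs to exactly one cell — the margin rule of counting only one
    side of each field-of-view boundary, with no double counting.
    """
    g = grid_side
    ix = np.minimum((coords[:, 0] * g).astype(np.int64), g - 1)
    iy = np.minimum((coords[:, 1] * g).astype(np.int64), g - 1)
    return np.bincount(iy * g + ix, minlength=g * g)


def _resolve_counts(cfg: SimConfig) -> tuple[int, float, OptimalAllocation]:
    dp = cfg.design_point()
    a = cfg.omega / dp.density + 1.0 + 1.0 / dp.u_hat
    if cfg.x_stop is not None:
        x_stop = int(cfg.x_stop)
    else:
        x_stop = max(int(math.floor(cfg.effort_budget / a + 0.5)), 1)
    budget = a * x_stop
    alloc = optimal_allocation(dp, budget)
    if alloc.n3c + alloc.n3e > cfg.n_cells:
        raise ValueError("planned fields of view exceed the grid")
    return x_stop, budget, alloc


def linear_window_count(
    area: StudyArea, x_stop: int, cfg: SimConfig
) -> ReplicateResult:
    """Linear-method replicate on a concrete study area.

    The window is a horizontal strip of ``window_height_fovs`` field-of-
    view rows anchored at the bottom edge; targets are swept in order of
    increasing horizontal coordinate and the window closes at the
    ``x_stop``-th target.  Markers strictly inside the half-open window
    are counted.
    """
    h = cfg.window_height_fovs / cfg.grid_side
    tx = area.target_coords[area.target_coords[:, 1] < h, 0]
    if tx.size < x_stop:
        raise ValueError(
            f"window strip holds only {tx.size} targets; "
            f"{x_stop} requested — increase window_height_fovs"
        )
    length = np.partition(tx, x_stop - 1)[x_stop - 1]
    marks = area.marker_coords
    n = int(np.count_nonzero((marks[:, 1] < h) & (marks[:, 0] < length)))
    return _linear_result(cfg, x_stop, n)


def _linear_result(cfg: SimConfig, x: int, n: int) -> ReplicateResult:
    k = cfg.n_markers  # exact spike: N1 * Y1
    t = cfg.dose_error_term
    c_raw = x * k / n if n > 0 else math.nan
    c_unb = (x - 1) * (k + 1) / (n + 1)
    sigma = 100.0 * math.sqrt(t + 1.0 / x + 1.0 / n) if n > 0 else math.nan
    density = cfg.n_targets / cfg.n_cells  # realised whole-grid density
    effort = cfg.omega * x / density + x + n
    return ReplicateResult("linear", c_raw, c_unb, sigma, effort, x, n)


def fov_replicate(
    area: StudyArea,
    n3c: int,
    n3e: int,
    cfg: SimConfig,
    cell_seed: int = 0,
) -> ReplicateResult:
    """FOVS-method replicate on a concrete study area.

    Draws ``n3c + n3e`` distinct cells uniformly without replacement from
    the grid; the first ``n3c`` form the calibration set (targets counted
    per cell), the rest the extrapolation set (markers counted in bulk).
    """
    if n3c < 2:
        raise ValueError("at least 2 calibration fields of view required")
    if n3c + n3e > cfg.n_cells:
        raise ValueError("requested more fields of view than the grid holds")
    rng = _rng(cfg, 1, cell_seed)
    cells = rng.choice(cfg.n_cells, size=n3c + n3e, replace=False)
    tcounts = per_fov_counts(area.target_coords, cfg.grid_side)
    mcounts = per_fov_counts(area.marker_coords, cfg.grid_side)
    calib = tcounts[cells[:n3c]]
    n = int(mcounts[cells[n3c:]].sum())
    return _fov_result(cfg, calib.astype(np.int64), n, n3c, n3e)


def _fov_result(
    cfg: SimConfig, calib: np.ndarray, n: int, n3c: int, n3e: int
) -> ReplicateResult:
    if calib.sum() == 0:
        raise ValueError("no common specimens observed in calibration counts")
    k = cfg.n_markers
    t = cfg.dose_error_term
    y3 = float(calib.mean())
    s3 = float(calib.std(ddof=1))
    s3p = s3 / (c4_factor(n3c) * y3)
    fpc = fpc_factor(cfg.n_cells, n3c)
    x_hat = y3 * n3e
    c_raw = x_hat * k / n if n > 0 else math.nan
    c_unb = x_hat * (k + 1) / (n + 1)
    sigma = (
        100.0 * math.sqrt(t + (fpc * s3p) ** 2 / n3c + 1.0 / n)
        if n > 0
        else math.nan
    )
    x_cal = int(calib.sum())
    effort = cfg.omega * n3c + x_cal + cfg.omega * n3e + n
    return ReplicateResult("fovs", c_raw, c_unb, sigma, effort, x_cal, n, n3c, n3e)


def _summarise(
    method: str,
    c_raw: np.ndarray,
    c_unb: np.ndarray,
    sigma: np.ndarray,
    effort: np.ndarray,
    valid: np.ndarray,
    c_true: float,
    bias_correction: bool,
) -> SimSummary:
    """Reduce replicate vectors to a summary.

    With the Chapman correction enabled, every structurally valid
    replicate contributes (zero-rare replicates included); otherwise the
    textbook ratio is undefined at n = 0 and those replicates are
    excluded and counted.
    """
    n_total = valid.size
    has_rare = np.isfinite(c_raw)
    if bias_correction:
        keep = valid
        c = c_unb
    else:
        keep = valid & has_rare
        c = c_raw
    kept = int(keep.sum())
    if kept == 0:
        raise ValueError("no valid replicates to summarise")
    rel = (c[keep] - c_true) / c_true
    sig_keep = keep & np.isfinite(sigma)
    return SimSummary(
        method=method,
        mean_c=float(c[keep].mean()),
        mean_sigma_pct=float(sigma[sig_keep].mean()),
        empirical_sigma_pct=float(100.0 * np.sqrt(np.mean(rel**2))),
        mean_effort=float(effort[keep].mean()),
        n_replicates=kept,
        n_excluded=int(n_total - kept),
        zero_rare_rate=float((valid & ~has_rare).sum() / max(valid.sum(), 1)),
    )


def _fast_batches(n: int, batch: int = 20_000) -> Iterator[tuple[int, int]]:
    start = 0
    while start < n:
        stop = min(start + batch, n)
        yield start, stop
        start = stop


def run_experiment(
    cfg: SimConfig, engine: Literal["fast", "area"] = "fast"
) -> ExperimentResult:
    """Run the paired linear/FOVS experiment over ``cfg.iterations``
    fresh study areas and summarise accuracy, precision and effort.

    The FOVS effort budget is set to the (expected) linear effort
    ``A * x_stop`` and split by the optimal-allocation formula, mirroring
    the matched-effort validation design.  Fully deterministic in
    ``cfg.seed``.
    """
    x_stop, budget, alloc = _resolve_counts(cfg)
    c_true = float(cfg.n_targets)
    if engine == "area":
        lin, fov = _run_area(cfg, x_stop, alloc)
    else:
        lin, fov = _run_fast(cfg, x_stop, alloc)
    lin_summary = _summarise(
        "linear", *lin, c_true=c_true, bias_correction=cfg.bias_correction
    )
    fov_summary = _summarise(
        "fovs", *fov, c_true=c_true, bias_correction=cfg.bias_correction
    )
    return ExperimentResult(
        config=cfg,
        x_stop=x_stop,
        effort_budget=budget,
        allocation=alloc,
        linear=lin_summary,
        fovs=fov_summary,
        true_concentration=c_true,
    )


_Vectors = tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]


def _run_area(
    cfg: SimConfig, x_stop: int, alloc: OptimalAllocation
) -> tuple[_Vectors, _Vectors]:
    it = cfg.iterations
    out = {
        m: [np.full(it, np.nan) for _ in range(4)] + [np.ones(it, dtype=bool)]
        for m in ("linear", "fovs")
    }
    for i in range(it):
        area = generate_study_area(cfg, i)
        try:
            rl = linear_window_count(area, x_stop, cfg)
            _store(out["linear"], i, rl)
        except ValueError:
            out["linear"][4][i] = False
        try:
            rf = fov_replicate(area, alloc.n3c, alloc.n3e, cfg, cell_seed=i)
            _store(out["fovs"], i, rf)
        except ValueError:
            out["fovs"][4][i] = False
    return tuple(out["linear"]), tuple(out["fovs"])  # type: ignore[return-value]


def _store(slot: list[np.ndarray], i: int, r: ReplicateResult) -> None:
    slot[0][i] = r.c_hat
    slot[1][i] = r.c_hat_unbiased
    slot[2][i] = r.sigma_hat_pct
    slot[3][i] = r.effort


def _run_fast(
    cfg: SimConfig, x_stop: int, alloc: OptimalAllocation
) -> tuple[_Vectors, _Vectors]:
    it = cfg.iterations
    rng = _rng(cfg, 2)
    k = cfg.n_markers
    t = cfg.dose_error_term
    n_cells = cfg.n_cells
    density = cfg.n_targets / n_cells

    # --- linear method: strip -> order statistic -> thinned markers ----
    h = cfg.window_height_fovs / cfg.grid_side
    m_t = rng.binomial(cfg.n_targets, h, size=it)
    valid_l = m_t >= x_stop
    # Beta(x_stop, M - x_stop + 1) is the x_stop-th smallest of M uniforms
    b_param = np.where(valid_l, m_t - x_stop + 1, 1)
    length = rng.beta(x_stop, b_param)
    m_n = rng.binomial(cfg.n_markers, h, size=it)
    n_l = rng.binomial(m_n, np.clip(length, 0.0, 1.0))
    with np.errstate(divide="ignore"):
        c_raw_l = np.where(n_l > 0, x_stop * k / np.maximum(n_l, 1), np.nan)
        sigma_l = np.where(
            n_l > 0,
            100.0 * np.sqrt(t + 1.0 / x_stop + 1.0 / np.maximum(n_l, 1)),
            np.nan,
        )
    c_unb_l = (x_stop - 1) * (k + 1) / (n_l + 1.0)
    effort_l = cfg.omega * x_stop / density + x_stop + n_l
    lin: _Vectors = (c_raw_l, c_unb_l, sigma_l, effort_l.astype(float), valid_l)

    # --- FOVS method: multinomial cells + binomial extrapolation -------
    n3c, n3e = alloc.n3c, alloc.n3e
    p = np.full(n3c + 1, 1.0 / n_cells)
    p[-1] = 1.0 - n3c / n_cells
    y3 = np.empty(it)
    s3 = np.empty(it)
    x_cal = np.empty(it)
    for lo, hi in _fast_batches(it):
        counts = rng.multinomial(cfg.n_targets, p, size=hi - lo)[:, :-1]
        x_cal[lo:hi] = counts.sum(axis=1)
        y3[lo:hi] = counts.mean(axis=1)
        s3[lo:hi] = counts.std(axis=1, ddof=1)
    n_f = rng.binomial(cfg.n_markers, n3e / n_cells, size=it)
    valid_f = x_cal > 0
    s3p = s3 / (c4_factor(n3c) * np.where(valid_f, y3, 1.0))
    fpc = fpc_factor(n_cells, n3c)
    x_hat = y3 * n3e
    with np.errstate(divide="ignore"):
        c_raw_f = np.where(n_f > 0, x_hat * k / np.maximum(n_f, 1), np.nan)
        sigma_f = np.where(
            n_f > 0,
            100.0
            * np.sqrt(t + (fpc * s3p) ** 2 / n3c + 1.0 / np.maximum(n_f, 1)),
            np.nan,
        )
    c_unb_f = x_hat * (k + 1) / (n_f + 1.0)
    effort_f = cfg.omega * (n3c + n3e) + x_cal + n_f
    fov: _Vectors = (c_raw_f, c_unb_f, sigma_f, effort_f, valid_f)
    return lin, fov


def error_vs_effort_sweep(
    cfg: SimConfig,
    x_stops: list[int],
    engine: Literal["fast", "area"] = "fast",
) -> list[ExperimentResult]:
    """Matched-effort experiments over a range of linear target counts —
    the raw material for precision-versus-effort curves."""
    results = []
    for i, x in enumerate(x_stops):
        sub = replace(cfg, x_stop=x, effort_budget=None, seed=cfg.seed + i)
        results.append(run_experiment(sub, engine=engine))
    return results
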