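"""Readers, writers, batch estimation and fixture generation.

Canonical interchange is delimited text (CSV).  Three tables are used:

``linear`` (one row per sample)
    sample_id, x, n, n_doses, mean_per_dose, sd_per_dose, sample_size,
    size_unit[, mean_targets_per_fov]
``calibration`` (long format, one row per calibration field of view)
    sample_id, fov_index, count
``extrapolation`` (one row per FOVS sample)
    sample_id, n_fov_extrap, rare_count, n_doses, mean_per_dose,
    sd_per_dose, sample_size, size_unit[, role]

A best-effort reader for the published supplementary spreadsheet layout
(one workbook row per sample carrying both methods' parameters) maps
recognised column names onto the same tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .design import DesignPoint, choose_method
from .estimators import (
    FovCalibration,
    FovExtrapolation,
    LinearTally,
    MarkerSpike,
    Role,
    SampleSpec,
    estimate_fovs,
    estimate_linear,
)
from .simulator import (
    SimConfig,
    fov_replicate,
    generate_study_area,
    linear_window_count,
    per_fov_counts,
)

__all__ = [
    "CountTable",
    "RunManifest",
    "read_counts",
    "read_s3_style_workbook",
    "write_counts",
    "estimate_batch",
    "summarise_results",
    "generate_fixtures",
]

_LINEAR_COLUMNS = [
    "sample_id",
    "x",
    "n",
    "n_doses",
    "mean_per_dose",
    "sd_per_dose",
    "sample_size",
    "size_unit",
]
_CALIB_COLUMNS = ["sample_id", "fov_index", "count"]
_EXTRAP_COLUMNS = [
    "sample_id",
    "n_fov_extrap",
    "rare_count",
    "n_doses",
    "mean_per_dose",
    "sd_per_dose",
    "sample_size",
    "size_unit",
]


@dataclass
class CountTable:
    """Validated per-sample count records for one or both methods."""

    linear: pd.DataFrame | None = None
    calibration: pd.DataFrame | None = None
    extrapolation: pd.DataFrame | None = None

    def fov_sample_ids(self) -> list[str]:
        if self.extrapolation is None:
            return []
        return list(self.extrapolation["sample_id"].astype(str))

    def calibration_counts(self, sample_id: str) -> list[int]:
        if self.calibration is None:
            return []
        rows = self.calibration[
            self.calibration["sample_id"].astype(str) == str(sample_id)
        ].sort_values("fov_index")
        return [int(c) for c in rows["count"]]


@dataclass
class RunManifest:
    """Reproducibility record emitted next to every CLI output."""

    command: str
    seed: int | None
    config: dict[str, Any]
    inputs: dict[str, str] = field(default_factory=dict)
    package_version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def add_input(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.inputs[str(path)] = digest

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _require_columns(df: pd.DataFrame, needed: list[str], what: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns: {missing}")


def _check_nonnegative(df: pd.DataFrame, cols: list[str], what: str) -> None:
    for col in cols:
        bad = df.index[pd.to_numeric(df[col], errors="coerce") < 0].tolist()
        if bad:
            raise ValueError(
                f"{what} table: negative values in column '{col}' at rows {bad}"
            )
        nan = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        if nan:
            raise ValueError(
                f"{what} table: non-numeric values in column '{col}' at rows {nan}"
            )


def read_counts(
    linear_path: str | Path | None = None,
    calibration_path: str | Path | None = None,
    extrapolation_path: str | Path | None = None,
    dialect: str = ",",
) -> CountTable:
    """Read and validate count tables from delimited text files."""
    table = CountTable()
    if linear_path is not None:
        df = pd.read_csv(linear_path, sep=dialect)
        _require_columns(df, _LINEAR_COLUMNS, "linear")
        _check_nonnegative(
            df, ["x", "n", "n_doses", "mean_per_dose", "sd_per_dose"], "linear"
        )
        zero_markers = df.index[df["n"] == 0].tolist()
        if zero_markers:
            raise ValueError(
                f"linear table: zero marker counts at rows {zero_markers}; "
                "concentration is unbounded for these samples"
            )
        table.linear = df
    if calibration_path is not None:
        df = pd.read_csv(calibration_path, sep=dialect)
        _require_columns(df, _CALIB_COLUMNS, "calibration")
        _check_nonnegative(df, ["count"], "calibration")
        few = [
            sid
            for sid, grp in df.groupby("sample_id")
            if len(grp) < 2
        ]
        if few:
            raise ValueError(
                f"calibration table: samples with fewer than 2 fields of view: {few}"
            )
        table.calibration = df
    if extrapolation_path is not None:
        df = pd.read_csv(extrapolation_path, sep=dialect)
        _require_columns(df, _EXTRAP_COLUMNS, "extrapolation")
        _check_nonnegative(df, ["n_fov_extrap", "rare_count"], "extrapolation")
        table.extrapolation = df
    return table


def write_counts(table: CountTable, outdir: str | Path) -> dict[str, Path]:
    """Write a CountTable back to CSV files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in (
        ("linear", table.linear),
        ("calibration", table.calibration),
        ("extrapolation", table.extrapolation),
    ):
        if df is not None:
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            written[name] = path
    return written


_S3_COLUMN_MAP = {
    # recognised header fragments (lower-cased) -> canonical names
    "sample": "sample_id",
    "reg": "sample_id",
    "x": "x",
    "target": "x",
    "n": "n",
    "marker": "n",
    "lycopodium": "n",
    "n1": "n_doses",
    "tablet": "n_doses",
    "y1": "mean_per_dose",
    "s1": "sd_per_dose",
    "mass": "sample_size",
    "v": "sample_size",
}


def read_s3_style_workbook(
    path: str | Path,
    sheet: int | str = 0,
    column_map: dict[str, str] | None = None,
) -> CountTable:
    """Best-effort reader for the supplementary spreadsheet layout of the
    empirical case study (one row per sample, both methods' parameters,
    derived columns tolerated).  ``column_map`` overrides the automatic
    header matching with explicit ``{spreadsheet header: canonical}``."""
    raw = pd.read_excel(path, sheet_name=sheet)
    mapping: dict[str, str] = {}
    if column_map:
        mapping.update(column_map)
    else:
        for col in raw.columns:
            key = str(col).strip().lower()
            for frag, canon in _S3_COLUMN_MAP.items():
                if key == frag or key.startswith(frag + " ") or key.startswith(frag + "_"):
                    mapping.setdefault(col, canon)
                    break
    df = raw.rename(columns=mapping)
    keep = [c for c in _LINEAR_COLUMNS if c in df.columns]
    df = df[keep].copy()
    if "size_unit" not in df.columns:
        df["size_unit"] = "g"
    missing = [c for c in _LINEAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"could not identify workbook columns for: {missing}; "
            "pass an explicit column_map"
        )
    return CountTable(linear=df)


def estimate_batch(
    table: CountTable,
    omega: float = 2.0,
    asym: float = 1.0,
    decide: bool = False,
) -> pd.DataFrame:
    """Per-sample concentration results for every tagged method.

    Failures are isolated per row (reported in an ``error`` column) so a
    single malformed sample does not abort a batch.  With ``decide=True``
    a method-determination column is added for samples that have both a
    density estimate and a ratio estimate.
    """
    rows: list[dict[str, Any]] = []
    if table.linear is not None:
        for _, rec in table.linear.iterrows():
            rows.append(_linear_row(rec, table, omega, asym, decide))
    if table.extrapolation is not None:
        for _, rec in table.extrapolation.iterrows():
            rows.append(_fov_row(rec, table, omega, asym, decide))
    return pd.DataFrame(rows)


def _spike_from(rec: pd.Series) -> MarkerSpike:
    return MarkerSpike(
        n_doses=int(rec["n_doses"]),
        mean_per_dose=float(rec["mean_per_dose"]),
        sd_per_dose=float(rec["sd_per_dose"]),
    )


def _linear_row(
    rec: pd.Series, table: CountTable, omega: float, asym: float, decide: bool
) -> dict[str, Any]:
    sid = str(rec["sample_id"])
    out: dict[str, Any] = {"sample_id": sid, "method": "linear"}
    try:
        tally = LinearTally(targets=int(rec["x"]), markers=int(rec["n"]))
        spike = _spike_from(rec)
        sample = SampleSpec(
            total_size=float(rec["sample_size"]), size_unit=str(rec["size_unit"])
        )
        density = rec.get("mean_targets_per_fov")
        if (density is None or pd.isna(density)) and table.calibration is not None:
            counts = table.calibration_counts(sid)
            if counts:
                density = float(np.mean(counts))
        density = float(density) if density is not None and not pd.isna(density) else None
        res = estimate_linear(
            tally, spike, sample, omega=omega, mean_targets_per_fov=density, asym=asym
        )
        out.update(
            concentration=res.concentration,
            sigma_pct=res.total_error_pct,
            effort=res.effort,
            u_hat=tally.targets / tally.markers if tally.markers else np.nan,
            ci_low=res.approx_ci[0] if res.approx_ci else np.nan,
            ci_high=res.approx_ci[1] if res.approx_ci else np.nan,
        )
        if decide and density:
            u = tally.targets / tally.markers
            dp = DesignPoint(max(u, 1.0 / u), density, omega, spike.dose_error_term)
            out["recommended"] = choose_method(dp).recommended.value
    except Exception as exc:  # noqa: BLE001 - per-row isolation by contract
        out["error"] = str(exc)
    return out


def _fov_row(
    rec: pd.Series, table: CountTable, omega: float, asym: float, decide: bool
) -> dict[str, Any]:
    sid = str(rec["sample_id"])
    out: dict[str, Any] = {"sample_id": sid, "method": "fovs"}
    try:
        counts = table.calibration_counts(sid)
        if not counts:
            raise ValueError("no calibration counts found for sample")
        role = Role(str(rec.get("role", Role.targets_common.value)))
        calib = FovCalibration(per_fov_counts=tuple(counts), role=role)
        extrap = FovExtrapolation(
            n_fov=int(rec["n_fov_extrap"]), rare_count=int(rec["rare_count"])
        )
        spike = _spike_from(rec)
        sample = SampleSpec(
            total_size=float(rec["sample_size"]), size_unit=str(rec["size_unit"])
        )
        res = estimate_fovs(calib, extrap, spike, sample, omega=omega, asym=asym)
        rare_per_fov = extrap.rare_count / extrap.n_fov
        u = calib.mean_per_fov / rare_per_fov if rare_per_fov > 0 else np.nan
        out.update(
            concentration=res.concentration,
            sigma_pct=res.total_error_pct,
            effort=res.effort,
            u_hat=u,
            extrapolated_common=res.extrapolated_common,
            ci_low=res.approx_ci[0],
            ci_high=res.approx_ci[1],
        )
        if decide and np.isfinite(u):
            dp = DesignPoint(
                max(u, 1.0 / u), calib.mean_per_fov, omega, spike.dose_error_term
            )
            out["recommended"] = choose_method(dp).recommended.value
    except Exception as exc:  # noqa: BLE001
        out["error"] = str(exc)
    return out


def summarise_results(results: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Across-sample means per method (concentration, error, effort) —
    the comparison quantities of a two-method benchmark."""
    summary: dict[str, dict[str, float]] = {}
    ok = results[results["error"].isna()] if "error" in results.columns else results
    for method, grp in ok.groupby("method"):
        summary[str(method)] = {
            "n_samples": float(len(grp)),
            "mean_concentration": float(grp["concentration"].mean()),
            "mean_sigma_pct": float(grp["sigma_pct"].mean()),
            "mean_effort": float(grp["effort"].mean()),
        }
    return summary


def generate_fixtures(
    cfg: SimConfig, seed: int, outdir: str | Path, n_samples: int = 3
) -> dict[str, Path]:
    """Emit CSV count tables with known ground truth by sampling virtual
    study areas; deterministic in ``seed``.

    Each simulated sample contributes one linear tally and one FOVS
    record (optimal allocation at matched effort).  A ``truth.json``
    sidecar records the exact concentrations and the generator config.
    """
    from dataclasses import replace

    from .simulator import _resolve_counts  # shared planning logic

    cfg = replace(cfg, seed=seed)
    x_stop, budget, alloc = _resolve_counts(cfg)
    lin_rows, cal_rows, ext_rows = [], [], []
    for i in range(n_samples):
        sid = f"sim{i:03d}"
        area = generate_study_area(cfg, i)
        rl = linear_window_count(area, x_stop, cfg)
        rf = fov_replicate(area, alloc.n3c, alloc.n3e, cfg, cell_seed=i)
        spike = dict(
            n_doses=cfg.n_doses,
            mean_per_dose=cfg.n_markers / cfg.n_doses,
            sd_per_dose=cfg.dose_sd,
            sample_size=1.0,
            size_unit="arbitrary",
        )
        lin_rows.append(dict(sample_id=sid, x=rl.x, n=rl.n, **spike))
        # calibration counts are re-derived from the same cells for the table
        rng_cells = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 1, i])
        cells = rng_cells.choice(cfg.n_cells, size=alloc.n3c + alloc.n3e, replace=False)
        tcounts = per_fov_counts(area.target_coords, cfg.grid_side)
        for j, cell in enumerate(cells[: alloc.n3c]):
            cal_rows.append(dict(sample_id=sid, fov_index=j, count=int(tcounts[cell])))
        ext_rows.append(
            dict(sample_id=sid, n_fov_extrap=alloc.n3e, rare_count=rf.n, **spike)
        )
    table = CountTable(
        linear=pd.DataFrame(lin_rows),
        calibration=pd.DataFrame(cal_rows),
        extrapolation=pd.DataFrame(ext_rows),
    )
    written = write_counts(table, outdir)
    truth = {
        "true_concentration": float(cfg.n_targets),
        "true_ratio": cfg.u_true,
        "x_stop": x_stop,
        "effort_budget": budget,
        "n3c": alloc.n3c,
        "n3e": alloc.n3e,
        "seed": seed,
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
    }
    truth_path = Path(outdir) / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    written["truth"] = truth_path
    return written
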