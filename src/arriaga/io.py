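"""Reading and writing schedules and results as plain CSV / JSON.

Schedule CSV dialect: comma-delimited with a header row; required columns
``age_start`` and ``n`` (empty or ``+`` marks the open-ended final group);
then either ``deaths`` and ``exposure`` or ``rate`` (optionally ``rate_se``);
``ax`` is optional and filled by the default rule when absent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import AgeDecomposition, CauseDecomposition
from .lifetable import LifeTable
from .resampling import UncertaintyResult
from .schedules import AgeGrid, MortalitySchedule, default_nax

__all__ = ["read_schedule", "write_schedule", "write_table", "read_uncertainty"]

_FLOAT_FMT = "%.17g"  # full round-trip precision for float64


def _parse_widths(raw: pd.Series) -> np.ndarray:
    out = []
    for v in raw:
        if pd.isna(v) or str(v).strip() in ("", "+"):
            out.append(np.inf)
        else:
            out.append(float(v))
    return np.array(out)


def read_schedule(path: str | Path, name: str | None = None) -> MortalitySchedule:
    """Read a mortality schedule from CSV, validating as it goes.

    Errors name the offending row so malformed files are easy to fix.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"n": "string"})
    if "age_start" not in df.columns or "n" not in df.columns:
        raise ValueError(f"{path}: columns 'age_start' and 'n' are required")
    grid = AgeGrid(df["age_start"].to_numpy(dtype=float), _parse_widths(df["n"]))

    have_counts = {"deaths", "exposure"} <= set(df.columns)
    have_rates = "rate" in df.columns
    if not have_counts and not have_rates:
        raise ValueError(f"{path}: need either (deaths, exposure) or rate columns")

    if have_counts:
        deaths = df["deaths"].to_numpy(dtype=float)
        exposure = df["exposure"].to_numpy(dtype=float)
        for col, vals, bad in (("deaths", deaths, deaths < 0), ("exposure", exposure, exposure <= 0)):
            if np.any(bad):
                row = int(np.argmax(bad))
                raise ValueError(
                    f"{path}: invalid {col} in row {row + 2} (age_start={grid.starts[row]:g})"
                )
        rates = deaths / exposure
    else:
        rates = df["rate"].to_numpy(dtype=float)
        deaths = exposure = None
        if "exposure" in df.columns:
            exposure = df["exposure"].to_numpy(dtype=float)
            deaths = rates * exposure

    if np.any(~np.isfinite(rates)) or np.any(rates < 0):
        row = int(np.argmax(~np.isfinite(rates) | (rates < 0)))
        raise ValueError(f"{path}: invalid rate in row {row + 2} (age_start={grid.starts[row]:g})")

    if "ax" in df.columns:
        nax = df["ax"].to_numpy(dtype=float)
        fallback = default_nax(grid, rates)
        nax = np.where(np.isnan(nax), fallback, nax)
    else:
        nax = default_nax(grid, rates)

    rate_se = df["rate_se"].to_numpy(dtype=float) if "rate_se" in df.columns else None
    return MortalitySchedule(
        grid=grid, rates=rates, nax=nax, deaths=deaths, exposure=exposure,
        rate_se=rate_se, name=name or path.stem,
    )


def _widths_col(grid: AgeGrid) -> list[str]:
    return ["" if np.isinf(w) else f"{w:g}" for w in grid.widths]


def write_schedule(schedule: MortalitySchedule, path: str | Path) -> None:
    df = pd.DataFrame({"age_start": schedule.grid.starts, "n": _widths_col(schedule.grid)})
    if schedule.has_counts:
        df["deaths"] = schedule.deaths
        df["exposure"] = schedule.exposure
    df["rate"] = schedule.rates
    if schedule.rate_se is not None:
        df["rate_se"] = schedule.rate_se
    df["ax"] = schedule.nax
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_table(result, path: str | Path, format: str = "csv") -> None:
    """Write a LifeTable, AgeDecomposition, CauseDecomposition, or
    UncertaintyResult to delimited text (or JSON) at full float precision."""
    path = Path(path)
    if isinstance(result, UncertaintyResult):
        _write_uncertainty(result, path)
        return
    if isinstance(result, (LifeTable, AgeDecomposition, CauseDecomposition)):
        df = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        df = result
    else:
        raise TypeError(f"cannot write object of type {type(result).__name__}")
    if format == "json":
        path.write_text(df.to_json(orient="columns", double_precision=15))
    else:
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_uncertainty(result: UncertaintyResult, path: Path) -> None:
    def arr(v):
        return None if v is None else [None if not np.isfinite(x) else float(x) for x in np.atleast_1d(v)]

    payload = {
        "method": result.method,
        "reps": result.reps,
        "seed": result.seed,
        "ci_level": result.ci_level,
        "labels": list(result.labels),
        "estimate": arr(result.estimate),
        "se": arr(result.se),
        "ci_lower": arr(result.ci_lower),
        "ci_upper": arr(result.ci_upper),
        "n_failed": result.n_failed,
        "n_truncated": result.n_truncated,
    }
    path.write_text(json.dumps(payload, indent=2))


def read_uncertainty(path: str | Path) -> UncertaintyResult:
    d = json.loads(Path(path).read_text())

    def arr(v):
        return None if v is None else np.array([np.nan if x is None else x for x in v], dtype=float)

    return UncertaintyResult(
        labels=tuple(d["labels"]),
        se=arr(d["se"]),
        estimate=arr(d.get("estimate")),
        ci_lower=arr(d.get("ci_lower")),
        ci_upper=arr(d.get("ci_upper")),
        method=d["method"],
        reps=d["reps"],
        seed=d["seed"],
        ci_level=d["ci_level"],
        n_failed=d.get("n_failed", 0),
        n_truncated=d.get("n_truncated", 0),
    )
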