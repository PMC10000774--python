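"""CSV readers/writers and frame <-> domain-object conversions.

All files are plain UTF-8 CSV with a mandatory header row and period
decimal separators; numeric round-trips are lossless (full ``repr``
precision on write).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .designs import DesignMatrix, Factor, code_levels
from .desirability import DesirabilityGoal
from .modr import SpecWindow
from .rsm import CMA_NAMES, FittedModel, ResponseTable

__all__ = [
    "read_design_csv",
    "write_design_csv",
    "read_response_csv",
    "write_response_csv",
    "response_table_from_frame",
    "factors_from_records",
    "goals_from_records",
    "windows_from_records",
    "write_anova_csv",
]

_META_COLS = ("run_order", "run", "is_center", "replicate")


class SchemaError(ValueError):
    """A CSV or config file does not match the expected schema."""


def factors_from_records(records: list[dict]) -> list[Factor]:
    out = []
    for i, r in enumerate(records):
        try:
            out.append(
                Factor(
                    name=str(r["name"]),
                    low=float(r["low"]),
                    high=float(r["high"]),
                    units=str(r.get("units", "") or ""),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"factor entry {i + 1}: {exc}") from exc
    return out


def goals_from_records(records: list[dict]) -> list[DesirabilityGoal]:
    out = []
    for i, r in enumerate(records):
        try:
            out.append(
                DesirabilityGoal(
                    cma=str(r["cma"]),
                    goal=str(r["goal"]),
                    lower=float(r["lower"]),
                    upper=float(r["upper"]),
                    target=float(r["target"]) if r.get("target") is not None else None,
                    weight=float(r.get("weight", 1.0)),
                    importance=float(r.get("importance", 1.0)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"goal entry {i + 1}: {exc}") from exc
    return out


def windows_from_records(records: list[dict]) -> list[SpecWindow]:
    def opt(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return float(v)

    out = []
    for i, r in enumerate(records):
        try:
            out.append(SpecWindow(cma=str(r["cma"]), lsl=opt(r.get("lsl")), usl=opt(r.get("usl"))))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"window entry {i + 1}: {exc}") from exc
    return out


def write_design_csv(design: DesignMatrix, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design_csv(path, factors: list[Factor]) -> DesignMatrix:
    frame = pd.read_csv(path)
    return _design_from_frame(frame, factors, where=str(path))


def _design_from_frame(frame: pd.DataFrame, factors: list[Factor], where: str = "frame") -> DesignMatrix:
    missing = [f.name for f in factors if f.name not in frame.columns]
    if missing:
        raise SchemaError(f"{where}: missing factor column(s) {missing}")
    coded = np.column_stack(
        [code_levels(f, frame[f.name].to_numpy(dtype=float)) for f in factors]
    )
    n = len(frame)
    if "is_center" in frame.columns:
        is_center = frame["is_center"].to_numpy().astype(bool)
    else:
        is_center = np.all(np.isclose(coded, 0.0), axis=1)
    if "replicate" in frame.columns:
        replicate = frame["replicate"].to_numpy(dtype=int)
    else:
        # number repeats of identical coded rows 1..m in order of appearance
        replicate = np.ones(n, dtype=int)
        seen: dict[tuple, int] = {}
        for i in range(n):
            key = tuple(np.round(coded[i], 12))
            seen[key] = seen.get(key, 0) + 1
            replicate[i] = seen[key]
    if "run_order" in frame.columns:
        run_order = frame["run_order"].to_numpy(dtype=int)
    elif "run" in frame.columns:
        run_order = frame["run"].to_numpy(dtype=int)
    else:
        run_order = np.arange(1, n + 1)
    return DesignMatrix(
        factors=list(factors),
        coded=coded,
        is_center=is_center,
        replicate=replicate,
        run_order=run_order,
    )


def response_table_from_frame(
    frame: pd.DataFrame,
    factors: list[Factor],
    cma_names: list[str] | None = None,
    where: str = "frame",
) -> ResponseTable:
    """Build a ResponseTable from a flat run table (factors + CMA columns)."""
    design = _design_from_frame(frame, factors, where=where)
    if cma_names is None:
        cma_names = [c for c in frame.columns if c in CMA_NAMES]
        if not cma_names:
            raise SchemaError(f"{where}: no recognized CMA columns (expected any of {CMA_NAMES})")
    else:
        missing = [c for c in cma_names if c not in frame.columns]
        if missing:
            raise SchemaError(f"{where}: missing CMA column(s) {missing}")
    responses = frame[cma_names].astype(float).reset_index(drop=True)
    return ResponseTable(design=design, responses=responses)


def read_response_csv(
    path, factors: list[Factor], cma_names: list[str] | None = None
) -> ResponseTable:
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    return response_table_from_frame(frame, factors, cma_names, where=str(path))


def write_response_csv(table: ResponseTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_anova_csv(model: FittedModel, path) -> None:
    if model.anova is None:
        raise ValueError("model has no ANOVA table; call anova_table first")
    model.anova.to_csv(path, index=False)


def ensure_outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out
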