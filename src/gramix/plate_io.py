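"""Plate CSV readers/writers and raw-luminescence normalisation.

Dialect (long format, comma-separated, '.' decimal, UTF-8):
``sample_id, component_ids, concentration_M, replicate, response_pct``
with concentrations in molar scientific notation. Raw files carry
``response_rlu`` instead of ``response_pct`` and are normalised with
``100 * (signal - blank) / (E2max - blank)``.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .types import ResponseCurve

__all__ = ["PLATE_COLUMNS", "read_plate_csv", "write_plate_csv", "normalize_rlu",
           "read_recipe_csv"]

PLATE_COLUMNS = ["sample_id", "component_ids", "concentration_M", "replicate",
                 "response_pct"]
FLOAT_FMT = "%.10g"


def normalize_rlu(signal, blank: float, e2max: float):
    """Convert raw luminescence to % of the E2 maximum above blank."""
    if e2max <= blank:
        raise ValueError(f"E2 maximum ({e2max}) must exceed blank ({blank})")
    return 100.0 * (np.asarray(signal, dtype=float) - blank) / (e2max - blank)


def _frame_to_curves(df: pd.DataFrame, path: str) -> list[ResponseCurve]:
    errors = []
    neg = df[df["concentration_M"] <= 0]
    for idx in neg.index:
        errors.append(f"row {idx + 2}: non-positive concentration "
                      f"{df.loc[idx, 'concentration_M']!r}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    curves = []
    for sid, grp in df.groupby("sample_id", sort=True):
        pivot = grp.pivot_table(index="concentration_M", columns="replicate",
                                values="response_pct", aggfunc="mean")
        ragged = pivot.isna().any().any()
        comp = grp["component_ids"].iloc[0]
        meta = {"sample_id": str(sid), "component_ids": "" if pd.isna(comp) else str(comp),
                "ragged": bool(ragged), "source": path}
        curves.append(ResponseCurve(pivot.index.to_numpy(dtype=float),
                                    pivot.to_numpy(dtype=float), meta))
    return curves


def read_plate_csv(
    path: Union[str, Path],
    blank: Optional[float] = None,
    e2max: Optional[float] = None,
) -> list[ResponseCurve]:
    """Read a plate CSV into one ResponseCurve per sample.

    Files with a ``response_rlu`` column are raw-luminescence plates and are
    normalised using ``blank``/``e2max``; if those are not given they are
    derived from the plate itself (mean of ``blank`` sample wells and the
    maximum mean E2 response).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    raw = "response_rlu" in df.columns
    required = [c for c in PLATE_COLUMNS if c != "response_pct"] + (
        ["response_rlu"] if raw else ["response_pct"])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected {required}")
    df = df.copy()
    df["concentration_M"] = pd.to_numeric(df["concentration_M"], errors="raise")
    if raw:
        if blank is None:
            blank_rows = df[df["sample_id"].str.lower() == "blank"]
            if blank_rows.empty:
                raise ValueError(f"{path}: raw plate needs blank= or 'blank' sample rows")
            blank = float(blank_rows["response_rlu"].mean())
        if e2max is None:
            e2_rows = df[df["sample_id"] == "E2"]
            if e2_rows.empty:
                raise ValueError(f"{path}: raw plate needs e2max= or 'E2' sample rows")
            e2max = float(e2_rows.groupby("concentration_M")["response_rlu"]
                          .mean().max())
        df["response_pct"] = normalize_rlu(df["response_rlu"], blank, e2max)
    df = df[df["sample_id"].str.lower() != "blank"]
    return _frame_to_curves(df, str(path))


def write_plate_csv(curves: Iterable[ResponseCurve], path: Union[str, Path]) -> None:
    """Write curves in the long plate dialect (deterministic formatting)."""
    rows = []
    for curve in curves:
        sid = curve.meta.get("sample_id", "sample")
        comp = curve.meta.get("component_ids", "")
        for ci, conc in enumerate(curve.concentrations):
            for ri in range(curve.n_replicates):
                v = curve.responses[ci, ri]
                if np.isnan(v):
                    continue
                rows.append((sid, comp, conc, ri + 1, v))
    df = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_recipe_csv(path: Union[str, Path]) -> list[tuple[str, float]]:
    """Read a mixture recipe (component_id, fraction) CSV."""
    df = pd.read_csv(path)
    missing = [c for c in ("component_id", "fraction") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    recipe = [(str(r.component_id), float(r.fraction)) for r in df.itertuples()]
    total = sum(f for _, f in recipe)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{path}: fractions sum to {total}, expected 1")
    return recipe
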