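"""Curve CSV I/O and flat key-value configuration files.

Magnetometry curves travel as two-column CSV with unit-bearing headers —
``T_K,chiT_cm3Kmol`` for susceptibility, ``H_T,M_muB`` for magnetization —
plus optional ``sigma`` and ``#``-prefixed comment lines.  Values are
written with 12 significant digits so a write/read round trip is lossless
at working precision.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .magnetometry import MagnetometryCurve

__all__ = ["CurveFormatError", "read_curve_csv", "write_curve_csv",
           "read_config", "write_ground_truth"]

_KINDS = {
    ("T_K", "chiT_cm3Kmol"): "susceptibility",
    ("H_T", "M_muB"): "magnetization",
}
_HEADERS = {v: k for k, v in _KINDS.items()}


class CurveFormatError(ValueError):
    """Malformed magnetometry curve file."""


def read_curve_csv(path: str | Path) -> MagnetometryCurve:
    """Read a typed curve; the header names decide kind and units."""
    path = Path(path)
    text = path.read_text()
    meta: dict[str, str] = {}
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            k, _, v = line.lstrip("# ").partition("=")
            meta[k.strip()] = v.strip()
    try:
        df = pd.read_csv(_io.StringIO(text), comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise CurveFormatError(f"{path}: {exc}") from exc
    cols = tuple(df.columns[:2])
    if cols not in _KINDS:
        raise CurveFormatError(
            f"{path}: unknown columns {list(df.columns)}; expected one of "
            f"{[list(k) for k in _KINDS]}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric[list(cols)].isna().any(axis=1)
    if bad.any():
        # pandas indices count data rows; add header + preceding comments
        first = int(np.flatnonzero(bad.to_numpy())[0])
        data_rows = [
            i
            for i, ln in enumerate(text.splitlines(), start=1)
            if ln.strip() and not ln.startswith("#")
        ]
        lineno = data_rows[first + 1] if first + 1 < len(data_rows) else "?"
        raise CurveFormatError(f"{path}: malformed value on line {lineno}")
    kind = _KINDS[cols]
    sigma = numeric["sigma"].to_numpy() if "sigma" in df.columns else None
    temperature = float(meta["temperature_K"]) if "temperature_K" in meta else None
    try:
        return MagnetometryCurve(
            kind,
            numeric[cols[0]].to_numpy(),
            numeric[cols[1]].to_numpy(),
            temperature=temperature,
            sigma=sigma,
        )
    except ValueError as exc:
        raise CurveFormatError(f"{path}: {exc}") from exc


def write_curve_csv(curve: MagnetometryCurve, path: str | Path) -> Path:
    """Write a curve with unit-bearing headers and '#' metadata lines."""
    path = Path(path)
    cols = _HEADERS[curve.kind]
    with path.open("w") as fh:
        if curve.temperature is not None:
            fh.write(f"# temperature_K = {curve.temperature:.12g}\n")
        header = ",".join(cols) + (",sigma" if curve.sigma is not None else "")
        fh.write(header + "\n")
        for i in range(curve.abscissa.size):
            row = f"{curve.abscissa[i]:.12g},{curve.ordinate[i]:.12g}"
            if curve.sigma is not None:
                row += f",{curve.sigma[i]:.12g}"
            fh.write(row + "\n")
    return path


def read_config(path: str | Path, valid_keys: set[str] | None = None) -> dict[str, Any]:
    """Flat key-value (YAML) configuration; unknown keys are rejected."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    if valid_keys is not None:
        unknown = set(cfg) - valid_keys
        if unknown:
            raise ValueError(
                f"{path}: unknown keys {sorted(unknown)}; "
                f"valid keys are {sorted(valid_keys)}"
            )
    return cfg


def write_ground_truth(truth: dict[str, Any], path: str | Path) -> Path:
    """JSON sidecar recording the generator's ground truth."""
    path = Path(path)
    path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return path
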