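"""Readers and writers for the plain-text formats used across the package.

Supported formats: delimited numeric tables (CSV/TSV, one optional header
row), GROMACS-style XVG (``#`` comments and ``@`` directives kept as
metadata), the density-grid format for droplet maps, and JSON reports.
Numbers use a decimal point only; floats are written with full ``repr``
precision so write-then-read round-trips are exact to 1e-12 relative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .droplet import DensityField
from .errors import DataFormatError

__all__ = [
    "TableData",
    "read_table",
    "write_report",
    "read_density_grid",
    "write_density_grid",
]


@dataclass
class TableData:
    """Numeric columns plus preserved comment/directive metadata."""

    columns: list[np.ndarray]
    names: list[str] | None = None
    comments: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        names = self.names or [f"col{i}" for i in range(len(self.columns))]
        return pd.DataFrame(dict(zip(names, self.columns)))


_DELIMS = {"csv": ",", "tsv": "\t", "xvg": None}


def _guess_dialect(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    return suffix if suffix in _DELIMS else "csv"


def read_table(path, dialect: str | None = None) -> TableData:
    """Read a delimited numeric table (CSV, TSV or XVG).

    Lines starting with ``#`` or ``@`` are preserved as metadata.  A single
    leading non-numeric row is taken as the header.  Ragged rows and NaN
    cells are reported with their line/column location.
    """
    path = Path(path)
    if dialect is None:
        dialect = _guess_dialect(path)
    if dialect not in _DELIMS:
        raise DataFormatError(f"unknown table dialect {dialect!r}")
    delim = _DELIMS[dialect]
    comments: list[str] = []
    names: list[str] | None = None
    rows: list[list[float]] = []
    n_cols = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#") or line.startswith("@"):
                comments.append(line)
                continue
            tokens = [t for t in line.split(delim)] if delim else line.split()
            tokens = [t.strip() for t in tokens if t.strip() != ""]
            try:
                values = [float(t) for t in tokens]
            except ValueError:
                if rows or names is not None:
                    raise DataFormatError(
                        f"{path.name}:{lineno}: non-numeric data row {line!r}"
                    ) from None
                names = tokens
                continue
            for j, v in enumerate(values):
                if math.isnan(v):
                    raise DataFormatError(
                        f"{path.name}:{lineno}: NaN in column {j + 1}"
                    )
            if n_cols is None:
                n_cols = len(values)
            elif len(values) != n_cols:
                raise DataFormatError(
                    f"{path.name}:{lineno}: expected {n_cols} columns, "
                    f"got {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise DataFormatError(f"{path.name}: no numeric data rows")
    data = np.asarray(rows, dtype=float)
    if names is not None and len(names) != data.shape[1]:
        raise DataFormatError(
            f"{path.name}: header has {len(names)} fields for "
            f"{data.shape[1]} data columns"
        )
    return TableData(
        columns=[data[:, j] for j in range(data.shape[1])],
        names=names,
        comments=comments,
    )


def _fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def write_report(results, path, format: str = "csv") -> None:
    """Write results (a mapping or DataFrame) as CSV or JSON.

    Floats are emitted at full precision; ``write_report`` followed by
    ``read_table``/``json.load`` reproduces every value to 1e-12 relative.
    An empty input produces a header-only (or empty-object) file.
    """
    path = Path(path)
    if format == "json":
        if isinstance(results, pd.DataFrame):
            payload = results.to_dict(orient="list")
        else:
            payload = {
                k: (float(v) if isinstance(v, (float, np.floating)) else v)
                for k, v in dict(results).items()
            }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    if format != "csv":
        raise DataFormatError(f"unknown report format {format!r}")
    if isinstance(results, pd.DataFrame):
        lines = [",".join(map(str, results.columns))]
        for _, row in results.iterrows():
            lines.append(",".join(_fmt(v) for v in row))
    else:
        results = dict(results)
        lines = [",".join(map(str, results.keys()))]
        if results:
            lines.append(",".join(_fmt(v) for v in results.values()))
    path.write_text("\n".join(lines) + "\n")


# Density-grid format: '#'-prefixed 'key=value' header lines carrying the
# bin widths, substrate plane, bulk density and grid origin, followed by a
# whitespace-delimited matrix, rows = z ascending, columns = y.
_GRID_KEYS = ("dy", "dz", "z0", "rho_bulk")


def write_density_grid(field: DensityField, path) -> None:
    """Write a droplet density field in the plain-text grid format."""
    path = Path(path)
    header = [
        f"# {key}={getattr(field, key)!r}" for key in _GRID_KEYS
    ] + [f"# y_min={field.y_min!r}", f"# z_min={field.z_min!r}"]
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, field.grid, fmt="%.10g")


def read_density_grid(path) -> DensityField:
    """Read a droplet density field written by :func:`write_density_grid`."""
    path = Path(path)
    meta: dict[str, float] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        raise DataFormatError(
                            f"{path.name}:{lineno}: bad header value {val!r}"
                        ) from None
                continue
            data_lines.append(line)
    missing = [k for k in _GRID_KEYS if k not in meta]
    if missing:
        raise DataFormatError(
            f"{path.name}: missing grid header keys {missing}"
        )
    if not data_lines:
        raise DataFormatError(f"{path.name}: no grid rows")
    try:
        rows = [[float(t) for t in ln.split()] for ln in data_lines]
    except ValueError as exc:
        raise DataFormatError(f"{path.name}: bad grid cell ({exc})") from None
    if len({len(r) for r in rows}) != 1:
        raise DataFormatError(f"{path.name}: ragged grid rows")
    grid = np.asarray(rows, dtype=float)
    return DensityField(
        grid=grid,
        dy=meta["dy"],
        dz=meta["dz"],
        z0=meta["z0"],
        rho_bulk=meta["rho_bulk"],
        y_min=meta.get("y_min", 0.0),
        z_min=meta.get("z_min", 0.0),
    )
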