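"""Plain-text file I/O: observable curves, trajectories, parameter files.

Formats are deliberately minimal and MD-ecosystem friendly:

* curves: two-column numeric text; lines starting with ``#`` or ``@`` are
  ignored (xvg-compatible), or CSV with a ``t_ps,msd_nm2``-style header;
* trajectories: CSV/whitespace tables with columns t, x, y (ps, nm);
* parameters/config: flat ``key: value`` YAML documents.

Every file written carries a provenance header (command line, package
version, timestamp, seed when applicable) and explicit unit declarations.
"""

from __future__ import annotations

import datetime
import re
import sys
from pathlib import Path

import numpy as np
import yaml

from .curves import DEFAULT_UNITS, KINDS, ObservableCurve
from .errors import CurveParseError, ParameterDomainError
from .model import GLEParameters
from .trajectory import Trajectory2D

__all__ = [
    "read_curve",
    "write_curve",
    "read_trajectory",
    "write_trajectory",
    "read_parameters",
    "write_parameters",
]

_UNIT_RE = re.compile(r"^[#@]\s*units?\s*[:=]\s*(\S+)\s+(\S+)", re.IGNORECASE)
_KIND_RE = re.compile(r"^[#@]\s*kind\s*[:=]\s*(\w+)", re.IGNORECASE)
# CSV headers like "t_ps,msd_nm2"
_CSV_HEADER_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*,\s*([A-Za-z_]\w*)\s*$")


def _provenance_lines(extra: dict | None = None) -> list[str]:
    from . import __version__

    lines = [
        f"# created by glediff {__version__}",
        f"# command: {' '.join(sys.argv)}",
        f"# date: {datetime.datetime.now().isoformat(timespec='seconds')}",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def _split_header_unit(token: str):
    """'msd_nm2' -> ('msd', 'nm2'); 't_ps' -> ('t', 'ps')."""
    parts = token.split("_", 1)
    return (parts[0], parts[1]) if len(parts) == 2 else (token, "")


def read_curve(path, kind: str | None = None) -> ObservableCurve:
    """Read a two-column observable curve.

    Comment lines (``#``/``@``) are skipped; ``# units: ps nm^2`` and
    ``# kind: msd`` declarations, or a CSV header like ``t_ps,msd_nm2``,
    set metadata.  Defaults: kind msd, units (ps, nm^2).  Non-numeric rows
    raise :class:`CurveParseError` with the line number; times must be
    strictly increasing.
    """
    path = Path(path)
    times, values = [], []
    units = None
    file_kind = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(("#", "@")):
                m = _UNIT_RE.match(line)
                if m:
                    units = (m.group(1), m.group(2))
                m = _KIND_RE.match(line)
                if m and m.group(1).lower() in KINDS:
                    file_kind = m.group(1).lower()
                continue
            m = _CSV_HEADER_RE.match(line)
            if m and not line[0].isdigit():
                tname, vname = m.group(1), m.group(2)
                _, t_unit = _split_header_unit(tname)
                vkind, v_unit = _split_header_unit(vname)
                if vkind.lower() in KINDS:
                    file_kind = vkind.lower()
                if t_unit and v_unit:
                    units = (t_unit, v_unit)
                continue
            fields = re.split(r"[,\s]+", line)
            if len(fields) < 2:
                raise CurveParseError(
                    f"{path}:{lineno}: expected two columns, got {line!r}",
                    line=lineno,
                )
            try:
                t, v = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise CurveParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}", line=lineno
                ) from exc
            if not (np.isfinite(t) and np.isfinite(v)):
                raise CurveParseError(
                    f"{path}:{lineno}: non-finite value in row {line!r}",
                    line=lineno,
                )
            times.append(t)
            values.append(v)
    if not times:
        raise CurveParseError(f"{path}: no data rows")
    times = np.asarray(times)
    if np.any(np.diff(times) <= 0):
        raise CurveParseError(f"{path}: times are not strictly increasing")
    kind = kind or file_kind or "msd"
    return ObservableCurve(
        times, np.asarray(values), kind,
        units=units or DEFAULT_UNITS[kind],
        meta={"path": str(path)},
    )


def write_curve(curve: ObservableCurve, path, extra_meta: dict | None = None) -> None:
    """Write a curve as two-column text with provenance and unit headers."""
    path = Path(path)
    meta = dict(curve.meta)
    meta.update(extra_meta or {})
    lines = _provenance_lines(meta)
    lines.append(f"# kind: {curve.kind}")
    lines.append(f"# units: {curve.units[0]} {curve.units[1]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for t, v in zip(curve.times, curve.values):
            fh.write(f"{t:.17g} {v:.17g}\n")


def read_trajectory(path, mass: float = 1.0, label: str = "") -> Trajectory2D:
    """Read a t,x,y table (ps, nm) into a :class:`Trajectory2D`.

    ``# mass: <g/mol>`` and ``# label: <text>`` header comments override the
    arguments; the sampling step must be uniform.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(("#", "@")):
                m = re.match(r"^[#@]\s*mass\s*[:=]\s*([\d.eE+-]+)", line)
                if m:
                    mass = float(m.group(1))
                m = re.match(r"^[#@]\s*label\s*[:=]\s*(.+)$", line)
                if m:
                    label = m.group(1).strip()
                continue
            if re.match(r"^[A-Za-z]", line):  # header row like t_ps,x_nm,y_nm
                continue
            fields = re.split(r"[,\s]+", line)
            if len(fields) < 3:
                raise CurveParseError(
                    f"{path}:{lineno}: expected t,x,y columns", line=lineno
                )
            try:
                rows.append([float(f) for f in fields[:3]])
            except ValueError as exc:
                raise CurveParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}", line=lineno
                ) from exc
    if len(rows) < 2:
        raise CurveParseError(f"{path}: need at least two samples")
    arr = np.asarray(rows)
    return Trajectory2D(
        arr[:, 0], arr[:, 1:3], mass=mass, label=label or path.stem,
        meta={"path": str(path)},
    )


def write_trajectory(traj: Trajectory2D, path, extra_meta: dict | None = None) -> None:
    path = Path(path)
    meta = {"mass": traj.mass, "label": traj.label}
    meta.update(traj.meta)
    meta.update(extra_meta or {})
    lines = _provenance_lines(meta)
    lines.append("# units: ps nm nm")
    lines.append("t_ps,x_nm,y_nm")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for t, (x, y) in zip(traj.times, traj.positions):
            fh.write(f"{t:.17g},{x:.17g},{y:.17g}\n")


_PARAM_KEYS = {
    "M": "M", "mass": "M",
    "T": "T", "temperature": "T",
    "omega_s": "omega_s", "omega_p": "omega_p",
    "tau": "tau", "lam": "lam", "lambda": "lam",
    "nu": "nu", "delta": "delta", "dim": "dim",
}


def read_parameters(path) -> GLEParameters:
    """Read a flat key: value parameter file (YAML subset).

    Keys: M (g/mol), T (K), omega_s, omega_p (ps^-1), tau (ps), lam, nu,
    delta, dim.  ``lambda`` is accepted for lam; nu defaults to delta*lam
    (the Brownian constraint) when omitted.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CurveParseError(f"{path}: expected a flat key: value mapping")
    vals = {}
    for key, v in raw.items():
        norm = _PARAM_KEYS.get(str(key))
        if norm is None:
            raise ParameterDomainError(f"{path}: unknown parameter {key!r}")
        vals[norm] = v
    vals.setdefault("delta", 1.0)
    if "nu" not in vals:
        vals["nu"] = vals["delta"] * vals["lam"]
    vals["dim"] = int(vals.get("dim", 2))
    return GLEParameters(**vals)


def write_parameters(p: GLEParameters, path, extra: dict | None = None) -> None:
    doc = {
        "M": float(p.M), "T": float(p.T),
        "omega_s": float(p.omega_s), "omega_p": float(p.omega_p),
        "tau": float(p.tau), "lam": float(p.lam), "nu": float(p.nu),
        "delta": float(p.delta), "dim": int(p.dim),
    }
    header = "\n".join(_provenance_lines(extra)) + "\n"
    header += "# units: M g/mol; T K; omega_s, omega_p ps^-1; tau ps\n"
    with open(path, "w") as fh:
        fh.write(header)
        yaml.safe_dump(doc, fh, sort_keys=False)
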