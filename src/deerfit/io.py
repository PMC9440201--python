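"""Plain-text readers and writers for the pipeline's external formats.

Traces and distributions are two-column delimited text (whitespace or
comma, '#' comments); trace metadata travels in a JSON sidecar next to the
trace file; titration tables are 3/4-column text; fit reports are JSON.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np

from .distributions import DistanceDistribution, DistanceGrid
from .forward import DipolarTrace
from .globalfit import GlobalFitResult
from .titration import TitrationFit, TitrationSeries

__all__ = [
    "read_trace",
    "write_trace",
    "read_distribution",
    "write_distribution",
    "read_titration_table",
    "write_titration_table",
    "write_fit_report",
    "write_titration_report",
    "read_restraint_table",
]


def _read_columns(path) -> np.ndarray:
    text = Path(path).read_text()
    clean = "\n".join(
        line.replace(",", " ")
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )
    data = np.loadtxt(_io.StringIO(clean), ndmin=2)
    return data


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def read_trace(path, sidecar: bool = True) -> DipolarTrace:
    """Read a (t_µs, V) trace; metadata from `<path>.meta.json` if present."""
    data = _read_columns(path)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (t, V)")
    meta = {}
    sc = _sidecar_path(path)
    if sidecar and sc.exists():
        meta = json.loads(sc.read_text())
    return DipolarTrace(t=data[:, 0], V=data[:, 1], meta=meta)


def write_trace(trace: DipolarTrace, path, sidecar: bool = True) -> None:
    header = "DEER dipolar trace\ncolumns: t_us  V"
    np.savetxt(path, np.column_stack([trace.t, trace.V]), header=header)
    if sidecar and trace.meta:
        _sidecar_path(path).write_text(json.dumps(trace.meta, indent=1))


def read_distribution(path) -> DistanceDistribution:
    """Read a two-column (r_nm, P) distribution; renormalizes to unit
    integral on its own (uniform) grid."""
    data = _read_columns(path)
    r, p = data[:, 0], data[:, 1]
    step = float(np.mean(np.diff(r)))
    grid = DistanceGrid(float(r[0]), float(r[-1]), step)
    z = np.trapezoid(p, r)
    if z <= 0:
        raise ValueError(f"{path}: distribution has nonpositive integral")
    return DistanceDistribution(grid, np.interp(grid.values, r, p / z))


def write_distribution(dist: DistanceDistribution, path) -> None:
    np.savetxt(
        path,
        np.column_stack([dist.grid.values, dist.density]),
        header="distance distribution\ncolumns: r_nm  P_per_nm",
    )


def read_titration_table(path) -> TitrationSeries:
    """Read (pH, f, [sigma2], [direction]) rows; direction column optional."""
    text = Path(path).read_text()
    pH, f, s2, direction = [], [], [], None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        pH.append(float(parts[0]))
        f.append(float(parts[1]))
        if len(parts) > 2:
            try:
                s2.append(float(parts[2]))
            except ValueError:
                direction = parts[2]
        if len(parts) > 3:
            direction = parts[3]
    sigma2 = np.array(s2) if len(s2) == len(f) else None
    return TitrationSeries(np.array(pH), np.array(f), sigma2, direction=direction)


def write_titration_table(series: TitrationSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("# titration table\n# columns: pH  f  sigma2  direction\n")
        s2 = series.sigma2 if series.sigma2 is not None else np.zeros_like(series.f)
        for row in zip(series.pH, series.f, s2):
            fh.write(f"{row[0]:.4f}  {row[1]:.6f}  {row[2]:.6f}  {series.direction}\n")


def write_fit_report(result: GlobalFitResult, path, include_bands: bool = True) -> None:
    """Serialize a global fit (parameters, criterion table, bands) as JSON."""
    report = result.to_dict()
    report["grid"] = {
        "r_min": result.grid.r_min,
        "r_max": result.grid.r_max,
        "step": result.grid.step,
    }
    if include_bands and result.covariance is not None:
        bands = {}
        for c, label in enumerate(result.condition_labels):
            lo, hi = result.confidence_band(condition=c)
            bands[label] = {
                "best_fit": result.distribution(c).density.tolist(),
                "lower_2sigma": lo.tolist(),
                "upper_2sigma": hi.tolist(),
            }
        report["bands"] = bands
    Path(path).write_text(json.dumps(report, indent=1))


def write_titration_report(fit: TitrationFit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=1))


def read_restraint_table(path):
    """Read (site1, site2, target_nm, k) rows into a RestraintSet."""
    from .geometry import Restraint, RestraintSet

    restraints = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 3:
            raise ValueError(f"restraint line needs >= 3 fields: {line!r}")
        k = float(parts[3]) if len(parts) > 3 else 10.0
        restraints.append(Restraint(parts[0], parts[1], float(parts[2]), k))
    return RestraintSet(restraints)
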