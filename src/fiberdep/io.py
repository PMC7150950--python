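"""Text-based outputs: legacy ASCII VTK, CSV tables, run manifest."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_vtk_points",
    "write_vtk_centerlines",
    "write_manifest",
    "export_results",
]

_FLOAT_FMT = "%.9g"


def write_vtk_points(path, points: np.ndarray, scalars: dict | None = None,
                     title: str = "points") -> None:
    """Legacy ASCII VTK PolyData point cloud with optional point scalars."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET POLYDATA", f"POINTS {n} double"]
    lines += [" ".join(_FLOAT_FMT % v for v in p) for p in points]
    lines.append(f"VERTICES {n} {2 * n}")
    lines += [f"1 {i}" for i in range(n)]
    if scalars:
        lines.append(f"POINT_DATA {n}")
        for name, vals in scalars.items():
            vals = np.asarray(vals)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [_FLOAT_FMT % v for v in vals]
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_centerlines(path, domain, title: str = "centerlines") -> None:
    """Segment centrelines as VTK PolyData lines with radius point data."""
    pts, cells, radii = [], [], []
    for i in range(domain.n_segments):
        a = domain.origins[i]
        b = a + domain.lengths[i] * domain.dirs[i]
        cells.append((len(pts), len(pts) + 1))
        pts += [a, b]
        radii += [domain.radii[i]] * 2
    n = len(pts)
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET POLYDATA", f"POINTS {n} double"]
    lines += [" ".join(_FLOAT_FMT % v for v in p) for p in pts]
    lines.append(f"LINES {len(cells)} {3 * len(cells)}")
    lines += [f"2 {a} {b}" for a, b in cells]
    lines.append(f"POINT_DATA {n}")
    lines.append("SCALARS radius double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [_FLOAT_FMT % r for r in radii]
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path, config, extra: dict | None = None) -> None:
    """Reproducibility record: configuration, seed and versions."""
    import fiberdep
    import scipy
    manifest = {
        "package": "fiberdep",
        "version": fiberdep.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True)
                          + "\n")


def export_results(result, outdir) -> dict:
    """Write DE table, deposition records, deposition maps and manifest.

    Outputs are deterministic byte-for-byte for a fixed config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    de = result.de_table()
    paths["de_table"] = outdir / "de_table.csv"
    de.to_csv(paths["de_table"], index=False, float_format=_FLOAT_FMT)

    paths["records"] = outdir / "deposition_records.csv"
    result.records.to_csv(paths["records"], index=False,
                          float_format=_FLOAT_FMT)

    # deposition maps with dispersion-index scalars
    from .sweep import dispersion_index
    for domname, radius in (("upper", 10e-3), ("tree", 5e-3)):
        sub = result.records[result.records["domain"] == domname]
        pts = sub[["x", "y", "z"]].to_numpy()
        counts = dispersion_index(pts, radius) if len(pts) else np.empty(0)
        p = outdir / f"deposition_map_{domname}.vtk"
        write_vtk_points(p, pts if len(pts) else np.empty((0, 3)),
                         {"neighbor_count": counts},
                         title=f"deposition map ({domname})")
        paths[f"map_{domname}"] = p

    paths["manifest"] = outdir / "manifest.json"
    write_manifest(paths["manifest"], result.config,
                   {"handoff_scale": result.handoff[0],
                    "handoff_delay_s": result.handoff[1]})
    return paths
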