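"""Configuration, field/mesh export and result reporting.

Units are fixed package-wide: mm, N, MPa, degC.  Configs round-trip through
YAML or JSON with a strict schema (unknown keys rejected).  Contact fields
export to legacy-VTK point data or CSV; meshes to STL or VTK.  All packaged
tables load offline; importing the package triggers no downloads.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .contact import ContactField
from .geometry import SurfacePatch
from .scenario import SimulationResult

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "export_field",
    "read_field_csv",
    "read_field_vtk",
    "export_mesh",
    "report",
]


class RunConfig(BaseModel):
    """Validated run configuration with the package defaults filled in."""

    model_config = ConfigDict(extra="forbid")

    knee: str | dict[str, float] = "mean"
    technique: str = "anatomic"
    graft: str | None = None
    angles: list[float] = Field(default_factory=lambda: [0.0, 30.0, 60.0, 90.0, 120.0])
    reference_angle: float = 40.0
    friction: float = 0.02
    approach: float = 0.5
    adjustment: float = 0.1
    patellar_thickness: float = 3.0
    femoral_thickness: float = 3.0
    cartilage_modulus: float = 10.0
    cartilage_poisson: float = 0.45
    element_size: float = 1.0
    residual_tol_n: float = 0.01
    thermal_tol_mm: float = 0.01
    seed: int = 0
    out_dir: str = "results"


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.model_dump()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# -- contact-field I/O ----------------------------------------------------

def export_field(field: ContactField, path: str | Path,
                 format: Literal["vtk", "csv"] | None = None) -> Path:
    """Write a contact field as VTK POLYDATA point data or a CSV table.

    The written pressures are bit-exact (full repr precision) so that a
    re-import reproduces the field exactly.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".")
    if fmt == "csv":
        df = pd.DataFrame({
            "x_mm": field.nodes[:, 0], "y_mm": field.nodes[:, 1],
            "z_mm": field.nodes[:, 2],
            "pressure_mpa": field.pressure,
            "penetration_mm": field.penetration,
            "facet": np.where(field.medial, "medial", "lateral"),
        })
        df.to_csv(path, index=False, float_format="%.17g")
        return path
    if fmt == "vtk":
        _write_vtk_points(path, field)
        return path
    raise ValueError(f"unknown export format {fmt!r}")


def _write_vtk_points(path: Path, field: ContactField) -> None:
    n = len(field.nodes)
    lines = [
        "# vtk DataFile Version 3.0",
        "pfjsim contact field",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in field.nodes]
    lines += [
        f"POINT_DATA {n}",
        "SCALARS pressure double 1",
        "LOOKUP_TABLE default",
    ]
    lines += [f"{v:.17g}" for v in field.pressure]
    lines += ["SCALARS penetration double 1", "LOOKUP_TABLE default"]
    lines += [f"{v:.17g}" for v in field.penetration]
    path.write_text("\n".join(lines) + "\n")


def read_field_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_field_vtk(path: str | Path) -> dict[str, np.ndarray]:
    """Minimal reader for the fields written by :func:`export_field`."""
    tokens = Path(path).read_text().splitlines()
    i = tokens.index(next(t for t in tokens if t.startswith("POINTS")))
    n = int(tokens[i].split()[1])
    points = np.array([[float(v) for v in tokens[i + 1 + k].split()] for k in range(n)])
    out = {"points": points}
    j = i + 1 + n
    while j < len(tokens):
        if tokens[j].startswith("SCALARS"):
            name = tokens[j].split()[1]
            vals = [float(tokens[j + 2 + k]) for k in range(n)]
            out[name] = np.array(vals)
            j += 2 + n
        else:
            j += 1
    return out


def export_mesh(patch: SurfacePatch, path: str | Path,
                format: Literal["stl", "vtk"] | None = None) -> Path:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".")
    if fmt == "stl":
        patch.as_trimesh().export(path)
        return path
    if fmt == "vtk":
        n, m = len(patch.nodes), len(patch.faces)
        lines = [
            "# vtk DataFile Version 3.0", "pfjsim surface", "ASCII",
            "DATASET POLYDATA", f"POINTS {n} double",
        ]
        lines += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in patch.nodes]
        lines.append(f"POLYGONS {m} {4 * m}")
        lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in patch.faces]
        path.write_text("\n".join(lines) + "\n")
        return path
    raise ValueError(f"unknown mesh format {fmt!r}")


# -- result reporting -----------------------------------------------------

def report(result: SimulationResult, out_dir: str | Path,
           stem: str = "simulation") -> dict[str, Path]:
    """Write the JSON summary and per-angle CSV for one simulation."""
    if not result.angles:
        raise ValueError("cannot report an empty simulation result")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = result.summary()
    csv_path = out_dir / f"{stem}.csv"
    table.to_csv(csv_path, index=False, float_format="%.10g")
    payload = {
        "technique": result.spec.technique,
        "graft": result.spec.graft,
        "bundle_config": result.spec.bundle_config,
        "config_hash": result.config_hash,
        "element_size_mm": result.element_size,
        "n_patellar_nodes": int(len(result.baseline.pressure)),
        "baseline_peak_mpa": result.baseline.peak(),
        "angles": json.loads(table.to_json(orient="records")),
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return {"csv": csv_path, "json": json_path}
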