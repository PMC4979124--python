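"""Readers and writers: TIFF stacks, JSON skeleton annotations, CSV tables.

File formats
------------
* **Stacks** are multi-page grayscale TIFFs (8/16-bit or float), pages in
  increasing z order. Voxel spacing is never trusted from TIFF tags (dialects
  vary); it comes from, in order of precedence: an explicit ``grid_override``,
  a YAML sidecar next to the stack (``<stem>.yaml`` with keys ``dx_um``,
  ``dy_um``, ``dz_um``), or the reference-acquisition defaults
  (0.178711 µm lateral, 0.46 µm axial) with a logged warning.
* **Annotations** are JSON with top-level keys ``grid``, ``nodes``, ``cells``,
  ``metadata`` (see :func:`read_annotations`); unknown keys are ignored with
  a warning.
* **Measurement tables** are CSV with the fixed header
  ``cell_id,length_um,width_um,is_branching``; a missing width is an empty
  field.
"""

from __future__ import annotations

import json
import logging
import math
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    AnnotationError,
    CellSegment,
    ConditionRecord,
    ConfigurationError,
    FormatError,
    HyphalSkeleton,
    ImageStack,
    SeptumNode,
    VoxelGrid,
)

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["cell_id", "length_um", "width_um", "is_branching"]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _spacing_from_sidecar(path: Path) -> Optional[tuple[float, float, float]]:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return None
    with open(sidecar) as fh:
        cfg = yaml.safe_load(fh) or {}
    try:
        return float(cfg["dx_um"]), float(cfg["dy_um"]), float(cfg["dz_um"])
    except KeyError as exc:
        raise ConfigurationError(
            f"sidecar {sidecar} is missing spacing key {exc}"
        ) from None


def read_stack(
    path: PathLike,
    grid_override: Optional[VoxelGrid] = None,
    allow_default_spacing: bool = True,
) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Pages are taken in file order as increasing z. Spacing precedence:
    ``grid_override`` > YAML sidecar > reference defaults (warned). Set
    ``allow_default_spacing=False`` to require an explicit spacing source.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected grayscale pages, got array of shape {arr.shape}"
        )
    nz, ny, nx = arr.shape

    if grid_override is not None:
        grid = grid_override
        if grid.shape != arr.shape:
            raise ConfigurationError(
                f"{path}: grid override shape {grid.shape} != stack {arr.shape}"
            )
    else:
        spacing = _spacing_from_sidecar(path)
        if spacing is None:
            if not allow_default_spacing:
                raise ConfigurationError(
                    f"{path}: no spacing sidecar and defaults disallowed"
                )
            logger.warning(
                "%s: no spacing information; falling back to reference "
                "acquisition spacing (0.178711, 0.178711, 0.46) µm",
                path,
            )
            default = VoxelGrid.paper_default()
            spacing = (default.dx, default.dy, default.dz)
        grid = VoxelGrid(nx=nx, ny=ny, nz=nz, dx=spacing[0], dy=spacing[1], dz=spacing[2])
    return ImageStack(intensities=arr, grid=grid)


def write_stack(stack: ImageStack, path: PathLike, write_sidecar: bool = True) -> None:
    """Write a stack as a multi-page TIFF plus a YAML spacing sidecar.

    Float arrays are scaled to the full 16-bit range; integer arrays are
    written unchanged. Deterministic: identical stacks yield identical bytes.
    """
    path = Path(path)
    arr = np.asarray(stack.intensities)
    if np.issubdtype(arr.dtype, np.floating):
        peak = float(arr.max())
        scale = 65535.0 / peak if peak > 0 else 1.0
        arr = np.clip(np.round(arr * scale), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")
    if write_sidecar:
        grid = stack.grid
        sidecar = _sidecar_path(path)
        sidecar.write_text(
            f"dx_um: {grid.dx!r}\ndy_um: {grid.dy!r}\ndz_um: {grid.dz!r}\n"
        )


# ---------------------------------------------------------------------------
# skeleton annotations (JSON)
# ---------------------------------------------------------------------------

_KNOWN_TOP_KEYS = {"grid", "nodes", "cells", "metadata"}


def read_annotations(path: PathLike) -> HyphalSkeleton:
    """Read a JSON skeleton annotation file.

    Schema::

        {"grid": {"nx":…, "ny":…, "nz":…, "dx_um":…, "dy_um":…, "dz_um":…},
         "nodes": [{"id":…, "x":…, "y":…, "z":…}, …],
         "cells": [{"id":…, "node_a":…, "node_b":…, "is_branching":…,
                    "waypoints": [[x,y,z], …]  (optional)}, …],
         "metadata": {…}}

    Unknown keys anywhere are ignored with a warning. Duplicate ids or
    unresolvable cell endpoints raise :class:`AnnotationError` listing every
    offending record.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: not valid JSON ({exc})") from exc

    unknown = set(doc) - _KNOWN_TOP_KEYS
    if unknown:
        logger.warning("%s: ignoring unknown top-level keys %s", path, sorted(unknown))

    problems: list[str] = []
    try:
        g = doc["grid"]
        grid = VoxelGrid(
            nx=int(g["nx"]), ny=int(g["ny"]), nz=int(g["nz"]),
            dx=float(g["dx_um"]), dy=float(g["dy_um"]), dz=float(g["dz_um"]),
        )
    except (KeyError, TypeError, ValueError, ConfigurationError) as exc:
        raise AnnotationError(f"{path}: bad or missing 'grid' section ({exc})") from exc

    nodes: list[SeptumNode] = []
    seen_nodes: set[str] = set()
    for rec in doc.get("nodes", []):
        try:
            node = SeptumNode(
                id=str(rec["id"]), x=float(rec["x"]), y=float(rec["y"]), z=float(rec["z"])
            )
        except (KeyError, TypeError, ValueError) as exc:
            problems.append(f"node record {rec!r}: {exc}")
            continue
        if node.id in seen_nodes:
            problems.append(f"node {node.id!r}: duplicate id")
        seen_nodes.add(node.id)
        nodes.append(node)

    cells: list[CellSegment] = []
    seen_cells: set[str] = set()
    for rec in doc.get("cells", []):
        try:
            waypoints = rec.get("waypoints")
            if waypoints is not None:
                waypoints = tuple(
                    (float(p[0]), float(p[1]), float(p[2])) for p in waypoints
                )
            cell = CellSegment(
                id=str(rec["id"]),
                node_a=str(rec["node_a"]),
                node_b=str(rec["node_b"]),
                is_branching=bool(rec.get("is_branching", False)),
                waypoints=waypoints,
            )
        except (KeyError, TypeError, ValueError, IndexError) as exc:
            problems.append(f"cell record {rec!r}: {exc}")
            continue
        if cell.id in seen_cells:
            problems.append(f"cell {cell.id!r}: duplicate id")
        seen_cells.add(cell.id)
        for endpoint in (cell.node_a, cell.node_b):
            if endpoint not in seen_nodes:
                problems.append(f"cell {cell.id!r}: unknown endpoint {endpoint!r}")
        cells.append(cell)

    if problems:
        raise AnnotationError(f"{path}: schema violations:\n  " + "\n  ".join(problems))

    return HyphalSkeleton(
        grid=grid, nodes=nodes, cells=cells, metadata=dict(doc.get("metadata", {}))
    )


def write_annotations(skeleton: HyphalSkeleton, path: PathLike) -> None:
    """Write a skeleton to the JSON annotation schema (deterministic bytes).

    Floats are serialized at full precision, so write→read is the identity
    on every coordinate.
    """
    grid = skeleton.grid
    doc = {
        "grid": {
            "nx": grid.nx, "ny": grid.ny, "nz": grid.nz,
            "dx_um": grid.dx, "dy_um": grid.dy, "dz_um": grid.dz,
        },
        "nodes": [
            {"id": n.id, "x": n.x, "y": n.y, "z": n.z} for n in skeleton.nodes
        ],
        "cells": [
            {
                "id": c.id,
                "node_a": c.node_a,
                "node_b": c.node_b,
                "is_branching": c.is_branching,
                **(
                    {"waypoints": [list(p) for p in c.waypoints]}
                    if c.waypoints is not None
                    else {}
                ),
            }
            for c in skeleton.cells
        ],
        "metadata": skeleton.metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# measurement tables (CSV)
# ---------------------------------------------------------------------------

def write_measurements(table: pd.DataFrame, path: PathLike) -> None:
    """Write a per-cell measurement table as CSV (missing widths empty)."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"measurement table lacks columns {missing}")
    out = table[MEASUREMENT_COLUMNS + [c for c in table.columns if c not in MEASUREMENT_COLUMNS]]
    out.to_csv(path, index=False, lineterminator="\n")


def read_measurements(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: measurement table lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# cultivation-condition fixture
# ---------------------------------------------------------------------------

def load_table1_fixture() -> list[ConditionRecord]:
    """The packaged per-condition morphometry/enzyme table (20 conditions).

    Two strains (QM9414 and the carbon-catabolite-derepressed cre1 knockout)
    on two carbon sources (wheat straw: 6 setups each; lactose: 4 setups
    each), with per-condition cell length/width (mean ± sd over 40 cells),
    branches per cell, filter-paper cellulase activity and extracellular
    protein. Lactose FPU values sat below the assay's detection limit and are
    stored as missing, never zero.
    """
    with resources.files("hyphamorph.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    records = []
    for row in df.itertuples(index=False):
        fpu = None if (isinstance(row.fpu_per_ml, float) and math.isnan(row.fpu_per_ml)) else float(row.fpu_per_ml)
        records.append(
            ConditionRecord(
                strain=row.strain,
                substrate=row.substrate,
                inoculation=row.inoculation,
                rpm=int(row.rpm),
                tween=bool(row.tween),
                length_mean=float(row.length_mean_um),
                length_sd=float(row.length_sd_um),
                width_mean=float(row.width_mean_um),
                width_sd=float(row.width_sd_um),
                branches_per_cell=float(row.branches_per_cell),
                fpu_per_ml=fpu,
                protein_g_per_l=float(row.protein_g_per_l),
            )
        )
    return records


def conditions_to_frame(records: list[ConditionRecord]) -> pd.DataFrame:
    """Condition records as a DataFrame (column order fixed)."""
    return pd.DataFrame(
        {
            "strain": [r.strain for r in records],
            "substrate": [r.substrate for r in records],
            "inoculation": [r.inoculation for r in records],
            "rpm": [r.rpm for r in records],
            "tween": [r.tween for r in records],
            "length_mean_um": [r.length_mean for r in records],
            "length_sd_um": [r.length_sd for r in records],
            "width_mean_um": [r.width_mean for r in records],
            "width_sd_um": [r.width_sd for r in records],
            "branches_per_cell": [r.branches_per_cell for r in records],
            "fpu_per_ml": [np.nan if r.fpu_per_ml is None else r.fpu_per_ml for r in records],
            "protein_g_per_l": [r.protein_g_per_l for r in records],
        }
    )
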