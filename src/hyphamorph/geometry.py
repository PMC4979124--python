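"""3D intercalary cell length and branching statistics from a skeleton.

Lengths are physical (µm) and fully anisotropic: voxel displacements are
scaled per axis by the grid spacing before the Euclidean norm, so axial
(z) distances — where the voxel is ~2.6× coarser than lateral — contribute
correctly. The default cell length is the straight 3D chord between the two
septum centres; if an annotation traces waypoints, the polyline length is
used instead.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    AnnotationError,
    CellSegment,
    ConfigurationError,
    HyphalSkeleton,
    ImageStack,
    UndefinedStatisticError,
)
from .io import MEASUREMENT_COLUMNS

logger = logging.getLogger(__name__)


def cell_polyline(cell: CellSegment, skeleton: HyphalSkeleton) -> np.ndarray:
    """Voxel-coordinate polyline node_a → waypoints → node_b, shape (k, 3)."""
    node_map = skeleton.node_map()
    try:
        a = node_map[cell.node_a]
        b = node_map[cell.node_b]
    except KeyError as exc:
        raise AnnotationError(
            f"cell {cell.id!r}: endpoint {exc} is not a known septum node"
        ) from None
    if cell.node_a == cell.node_b:
        raise AnnotationError(f"cell {cell.id!r}: degenerate self-loop")
    points = [a.position]
    if cell.waypoints:
        points.extend(np.asarray(w, dtype=float) for w in cell.waypoints)
    points.append(b.position)
    return np.vstack(points)


def cell_length(cell: CellSegment, skeleton: HyphalSkeleton) -> float:
    """Length of a cell in µm.

    Without waypoints this is the anisotropic Euclidean distance
    ``sqrt((Δx·dx)² + (Δy·dy)² + (Δz·dz)²)`` between the two septum centres;
    with waypoints, the summed µm length of the polyline through them.
    """
    polyline = cell_polyline(cell, skeleton)
    deltas_um = np.diff(polyline, axis=0) * skeleton.grid.spacing
    return float(np.sum(np.linalg.norm(deltas_um, axis=1)))


def branches_per_cell(skeleton: HyphalSkeleton) -> float:
    """Fraction of cells carrying a branch mark.

    A cell bearing several branches still contributes a single mark — the
    statistic counts branching cells, not branch tips.
    """
    if skeleton.n_cells == 0:
        raise UndefinedStatisticError("branches_per_cell undefined for 0 cells")
    marked = sum(1 for c in skeleton.cells if c.is_branching)
    return marked / skeleton.n_cells


def measure_all(
    skeleton: HyphalSkeleton,
    stack: Optional[ImageStack] = None,
    width_params=None,
) -> pd.DataFrame:
    """Measure every cell: length always, width when a stack is supplied.

    Returns a table with columns ``cell_id, length_um, width_um,
    is_branching`` (one row per cell, skeleton order). Width estimation
    failures are logged and left as NaN.
    """
    if stack is not None and stack.grid != skeleton.grid:
        raise ConfigurationError(
            f"stack grid {stack.grid.shape} does not match skeleton grid "
            f"{skeleton.grid.shape}"
        )

    from .widths import WidthParams, estimate_cell_width

    if width_params is None:
        width_params = WidthParams()

    rows = []
    for cell in skeleton.cells:
        length = cell_length(cell, skeleton)
        width = np.nan
        if stack is not None:
            estimate = estimate_cell_width(stack, cell, skeleton, width_params)
            if estimate is None:
                logger.info("cell %s: width estimation failed", cell.id)
            else:
                width = estimate
        rows.append((cell.id, length, width, cell.is_branching))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
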