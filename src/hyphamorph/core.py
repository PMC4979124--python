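"""Domain types for confocal z-stack morphometry of septate hyphae.

The measurement unit convention used throughout the package:

* voxel coordinates are 0-based and continuous, ordered ``(x, y, z)`` where
  ``x`` indexes columns, ``y`` rows and ``z`` slices of the stack array
  (which is itself indexed ``(z, y, x)``);
* physical positions are in micrometres and are obtained *only* through a
  :class:`VoxelGrid`, the single authority for voxel-to-µm conversion.

Sub-voxel positions are legal everywhere: a septum centre annotated on a
zoomed slice is naturally a fractional coordinate, and integer positions are
just a special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# lateral field of view of the reference acquisition: 183 µm over 1024 px
PAPER_LATERAL_UM = 183.0
PAPER_LATERAL_PX = 1024
PAPER_DX_UM = PAPER_LATERAL_UM / PAPER_LATERAL_PX  # 0.178711 µm
PAPER_DZ_UM = 0.46


class MorphometryError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MorphometryError):
    """An input file is not in the expected format."""


class ConfigurationError(MorphometryError):
    """Inconsistent or missing configuration (e.g. voxel spacing, grids)."""


class AnnotationError(MorphometryError):
    """A skeleton annotation file violates the schema."""


class UndefinedStatisticError(MorphometryError):
    """A statistic was requested on too few observations."""


class SingularFitError(MorphometryError):
    """A regression cannot be fitted (degenerate predictor)."""


class DegenerateGeometryError(MorphometryError):
    """A geometric operation on a degenerate object (e.g. zero-length cell)."""


class GenerationError(MorphometryError):
    """A synthetic scene cannot be generated with the given parameters."""


@dataclass(frozen=True)
class VoxelGrid:
    """Image dimensions plus physical voxel spacing.

    Parameters
    ----------
    nx, ny, nz
        Voxel counts along x (columns), y (rows) and z (slices).
    dx, dy
        Lateral spacing in µm per voxel.
    dz
        Axial spacing in µm per voxel.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "nz"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive voxel count")
        for name in ("dx", "dy", "dz"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive (µm/voxel)")

    @classmethod
    def paper_default(cls, nz: int = 60) -> "VoxelGrid":
        """The reference acquisition grid: 1024×1024 px = 183×183 µm, 0.46 µm z-step."""
        return cls(
            nx=PAPER_LATERAL_PX,
            ny=PAPER_LATERAL_PX,
            nz=nz,
            dx=PAPER_DX_UM,
            dy=PAPER_DX_UM,
            dz=PAPER_DZ_UM,
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(nz, ny, nx)`` of a stack on this grid."""
        return (self.nz, self.ny, self.nx)

    @property
    def spacing(self) -> np.ndarray:
        """Spacing ``(dx, dy, dz)`` in µm/voxel as an array."""
        return np.array([self.dx, self.dy, self.dz], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.nx, self.ny, self.nz], dtype=float)

    @property
    def extent_um(self) -> np.ndarray:
        """Physical size ``(X, Y, Z)`` of the imaged volume in µm."""
        return self.counts * self.spacing

    def contains(self, position: Sequence[float]) -> bool:
        p = np.asarray(position, dtype=float)
        return bool(np.all(p >= 0) and np.all(p <= self.counts - 1))

    def to_um(self, position: Sequence[float]) -> np.ndarray:
        """Convert a continuous voxel coordinate (x, y, z) to µm."""
        return np.asarray(position, dtype=float) * self.spacing

    def to_voxel(self, position_um: Sequence[float]) -> np.ndarray:
        """Convert a µm position (x, y, z) to continuous voxel coordinates."""
        return np.asarray(position_um, dtype=float) / self.spacing


@dataclass(frozen=True)
class SeptumNode:
    """Centre of a septum (cross-wall), in continuous 0-based voxel coordinates."""

    id: str
    x: float
    y: float
    z: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class CellSegment:
    """One intercalary cell: the stretch of hypha between two septa.

    ``waypoints`` optionally trace the curved centreline between the two
    septum centres (ordered from ``node_a`` to ``node_b``, voxel coordinates);
    without them the cell is treated as the straight chord.
    """

    id: str
    node_a: str
    node_b: str
    is_branching: bool = False
    waypoints: Optional[tuple[tuple[float, float, float], ...]] = None


@dataclass
class HyphalSkeleton:
    """An annotated 3D hyphal skeleton: septum nodes joined by cell segments.

    A node may be shared by several cells (branch points). Construction does
    not validate; use :func:`validate_skeleton` to obtain a violation report.
    """

    grid: VoxelGrid
    nodes: list[SeptumNode] = field(default_factory=list)
    cells: list[CellSegment] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def node_map(self) -> dict[str, SeptumNode]:
        """id → node lookup; on duplicate ids the last definition wins."""
        return {n.id: n for n in self.nodes}

    def node(self, node_id: str) -> SeptumNode:
        try:
            return self.node_map()[node_id]
        except KeyError:
            raise AnnotationError(f"unknown septum node id {node_id!r}") from None

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate_skeleton`."""

    rule: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.subject}: {self.message}"


def validate_skeleton(skeleton: HyphalSkeleton) -> list[Violation]:
    """Check all skeleton invariants; report violations, never raise.

    Returns an empty list iff the skeleton is valid. Each violation names the
    offending node or cell id and the rule it breaks.
    """
    violations: list[Violation] = []
    grid = skeleton.grid

    seen_nodes: set[str] = set()
    for node in skeleton.nodes:
        if node.id in seen_nodes:
            violations.append(
                Violation("unique-node-id", node.id, "duplicate septum node id")
            )
        seen_nodes.add(node.id)
        for axis, value, n in zip("xyz", node.position, grid.counts):
            if not (0 <= value <= n - 1):
                violations.append(
                    Violation(
                        "node-in-bounds",
                        node.id,
                        f"{axis}={value} outside [0, {n - 1:g}]",
                    )
                )

    node_ids = {n.id for n in skeleton.nodes}
    seen_cells: set[str] = set()
    for cell in skeleton.cells:
        if cell.id in seen_cells:
            violations.append(
                Violation("unique-cell-id", cell.id, "duplicate cell id")
            )
        seen_cells.add(cell.id)
        if cell.node_a == cell.node_b:
            violations.append(
                Violation("no-self-loop", cell.id, "node_a equals node_b")
            )
        for endpoint in (cell.node_a, cell.node_b):
            if endpoint not in node_ids:
                violations.append(
                    Violation(
                        "endpoint-resolves",
                        cell.id,
                        f"endpoint {endpoint!r} is not a known septum node",
                    )
                )
        if cell.waypoints is not None:
            for i, wp in enumerate(cell.waypoints):
                if not grid.contains(wp):
                    violations.append(
                        Violation(
                            "waypoint-in-bounds",
                            cell.id,
                            f"waypoint {i} at {tuple(wp)} outside the grid",
                        )
                    )
    return violations


def physical_position(node: SeptumNode, grid: VoxelGrid) -> np.ndarray:
    """Physical µm position ``(x·dx, y·dy, z·dz)`` of a septum node.

    Raises
    ------
    ConfigurationError
        If the node lies outside the grid, naming the offending axis.
    """
    for axis, value, n in zip("xyz", node.position, grid.counts):
        if not (0 <= value <= n - 1):
            raise ConfigurationError(
                f"node {node.id!r}: {axis}={value} outside [0, {n - 1:g}]"
            )
    return grid.to_um(node.position)


@dataclass(frozen=True)
class ImageStack:
    """A 3D intensity array (indexed z, y, x) bound to its voxel grid."""

    intensities: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise FormatError(f"stack must be 3D, got {arr.ndim}D")
        if arr.shape != self.grid.shape:
            raise ConfigurationError(
                f"stack shape {arr.shape} does not match grid {self.grid.shape}"
            )
        if np.issubdtype(arr.dtype, np.floating) and np.any(arr < 0):
            raise FormatError("stack intensities must be non-negative")


@dataclass(frozen=True)
class CellMeasurement:
    """Per-cell result: 3D intercalary length, optional width, branch mark."""

    cell_id: str
    length_um: float
    width_um: Optional[float]
    is_branching: bool

    def __post_init__(self) -> None:
        if self.length_um < 0:
            raise MorphometryError("length_um must be non-negative")
        if self.width_um is not None and not self.width_um > 0:
            raise MorphometryError("width_um must be positive when present")


@dataclass(frozen=True)
class ConditionRecord:
    """One cultivation condition: morphometry plus enzyme/protein readouts.

    ``fpu_per_ml`` is ``None`` when the filter-paper assay stayed below its
    detection limit (all lactose cultivations) — never zero.
    """

    strain: str
    substrate: str
    inoculation: str
    rpm: int
    tween: bool
    length_mean: float
    length_sd: float
    width_mean: float
    width_sd: float
    branches_per_cell: float
    fpu_per_ml: Optional[float]
    protein_g_per_l: float

    def __post_init__(self) -> None:
        if self.length_sd < 0 or self.width_sd < 0:
            raise MorphometryError("standard deviations must be non-negative")
        if self.branches_per_cell < 0:
            raise MorphometryError("branches_per_cell must be non-negative")


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares fit: slope, intercept, R², sample size."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise MorphometryError("regression needs n >= 2")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise MorphometryError("r_squared must lie in [0, 1]")
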