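"""Synthetic confocal z-stacks of septate, branching hyphae with ground truth.

The generator emulates the reference acquisition: a thin, laterally wide
volume (183×183 µm at 1024×1024 px, 0.46 µm z-steps) containing tube-like
hyphae whose chitinous walls fluoresce. Each hypha is grown as a persistent
random walk segmented into cells of lognormal length; branches spawn at
septa at 30–90° off the parent axis. The intensity field is

    background
    + wall shell   (Gaussian cross-section centred at radius = diameter/2
                    around the centreline)
    + septum disks (filled, perpendicular to the local axis),

convolved with a separable anisotropic Gaussian PSF (axially elongated, as
in confocal imaging), with optional Gaussian or Poisson noise applied last.

Geometry is computed in continuous µm space and stamped sub-voxel-exactly
(distance of every voxel centre to a densely sampled centreline), so the
exported ground truth — every septum, cell, branch mark, length and
diameter — is exact, not voxelized.

All randomness flows through a single generator seeded once per scene; the
draws occur in a fixed documented order (per hypha: start, direction, then
per cell: length, bending angles, then branch decisions and branch walks;
noise last), so a given seed is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    CellSegment,
    GenerationError,
    HyphalSkeleton,
    ImageStack,
    SeptumNode,
    VoxelGrid,
)
from . import io as hio

WAYPOINT_STEP_UM = 1.0   # arc-length step between walk waypoints (bending applied per step)
RENDER_STEP_UM = 0.1     # centreline sampling step for the distance field
FWHM_TO_SIGMA = 2 * np.sqrt(2 * np.log(2))


def _default_grid() -> VoxelGrid:
    return VoxelGrid.paper_default(nz=60)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic scene.

    Defaults follow the reference acquisition geometry and the measured
    morphology ranges (cell lengths ~8–17 µm, widths ~2.4–4 µm): mean cell
    length 10 µm at CV 0.3, tube diameter 3 µm, 0.3 µm wall. Intensities are
    arbitrary units. ``noise_model`` is one of ``"none"``, ``"gaussian"``
    (``noise_param`` = absolute sd) or ``"poisson"`` (``noise_param`` = photon
    scale: counts are drawn from Poisson(intensity × scale) / scale).
    """

    grid: VoxelGrid = field(default_factory=_default_grid)
    n_hyphae: int = 5
    mean_cell_length_um: float = 10.0
    cell_length_cv: float = 0.3
    tube_diameter_um: float = 3.0
    wall_thickness_um: float = 0.3
    branch_probability_per_cell: float = 0.2
    bending_sd_deg: float = 10.0
    wall_intensity: float = 200.0
    septum_intensity: float = 220.0
    background_intensity: float = 10.0
    psf_sigma_xy_um: float = 0.2
    psf_sigma_z_um: float = 0.6
    noise_model: str = "none"
    noise_param: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hyphae < 0:
            raise GenerationError("n_hyphae must be >= 0")
        for name in ("mean_cell_length_um", "tube_diameter_um", "wall_thickness_um",
                     "wall_intensity", "septum_intensity"):
            if not getattr(self, name) > 0:
                raise GenerationError(f"{name} must be positive")
        if not (0 <= self.branch_probability_per_cell <= 1):
            raise GenerationError("branch_probability_per_cell must lie in [0, 1]")
        if self.cell_length_cv <= 0:
            raise GenerationError("cell_length_cv must be positive")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise GenerationError(f"unknown noise model {self.noise_model!r}")


@dataclass
class GroundTruth:
    """Exported ground truth of a generated scene.

    ``records`` has one row per generated cell with columns
    ``cell_id, length_um, diameter_um, is_branching``.
    """

    skeleton: HyphalSkeleton
    records: pd.DataFrame


@dataclass
class _Scene:
    """Internal geometry: µm-space paths plus the annotation-level skeleton."""

    skeleton: HyphalSkeleton
    truth: pd.DataFrame
    paths: list  # list of (N, 3) µm polylines (rendered as wall tubes)
    septa: list  # list of (point µm, unit tangent) for septum disks


def _lognormal_lengths(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    sigma2 = np.log(1 + cv * cv)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _rotate(vector: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``vector`` by ``angle`` around unit ``axis``."""
    c, s = np.cos(angle), np.sin(angle)
    return (
        vector * c
        + np.cross(axis, vector) * s
        + axis * np.dot(axis, vector) * (1 - c)
    )


def _perpendicular(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector perpendicular to ``direction``."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(direction, helper)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(direction, helper)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    psi = rng.uniform(0, 2 * np.pi)
    return np.cos(psi) * u + np.sin(psi) * v


class _SkeletonBuilder:
    def __init__(self, grid: VoxelGrid):
        self.grid = grid
        self.nodes: list[SeptumNode] = []
        self.cells: list[CellSegment] = []
        self.truth_rows: list[tuple] = []
        self._node_counter = 0
        self._cell_counter = 0

    def add_node(self, point_um: np.ndarray) -> str:
        node_id = f"n{self._node_counter:04d}"
        self._node_counter += 1
        voxel = point_um / self.grid.spacing
        self.nodes.append(SeptumNode(id=node_id, x=voxel[0], y=voxel[1], z=voxel[2]))
        return node_id

    def add_cell(
        self,
        node_a: str,
        node_b: str,
        waypoints_um: list[np.ndarray],
        length_um: float,
        diameter_um: float,
    ) -> str:
        cell_id = f"c{self._cell_counter:04d}"
        self._cell_counter += 1
        waypoints = (
            tuple(tuple(p / self.grid.spacing) for p in waypoints_um)
            if waypoints_um
            else None
        )
        self.cells.append(
            CellSegment(id=cell_id, node_a=node_a, node_b=node_b, waypoints=waypoints)
        )
        self.truth_rows.append((cell_id, length_um, diameter_um, False))
        return cell_id

    def mark_branching(self, cell_id: str) -> None:
        for i, c in enumerate(self.cells):
            if c.id == cell_id:
                self.cells[i] = replace(c, is_branching=True)
        self.truth_rows = [
            (cid, l, d, True) if cid == cell_id else (cid, l, d, b)
            for (cid, l, d, b) in self.truth_rows
        ]


def _walk_hypha(
    rng: np.random.Generator,
    builder: _SkeletonBuilder,
    start: np.ndarray,
    direction: np.ndarray,
    params: SceneParams,
    lo: np.ndarray,
    hi: np.ndarray,
    max_cells: int,
) -> tuple[np.ndarray, list, list[str]]:
    """Grow one hypha; returns (path µm, septa [(point, tangent)], cell ids)."""
    bend_sd = np.deg2rad(params.bending_sd_deg)
    point = start.copy()
    d = direction / np.linalg.norm(direction)

    path = [point.copy()]
    septa = [(point.copy(), d.copy())]
    node_prev = builder.add_node(point)
    cell_ids: list[str] = []

    pending: list[np.ndarray] = []   # waypoints of the cell under construction
    arc_in_cell = 0.0
    target = float(_lognormal_lengths(rng, params.mean_cell_length_um, params.cell_length_cv, 1)[0])

    while len(cell_ids) < max_cells:
        axis = _perpendicular(d, rng)
        theta = rng.normal(0.0, bend_sd)
        d = _rotate(d, axis, theta)
        d /= np.linalg.norm(d)

        remaining = target - arc_in_cell
        step = min(WAYPOINT_STEP_UM, remaining)
        nxt = point + step * d
        if np.any(nxt < lo) or np.any(nxt > hi):
            break  # hypha hits the volume boundary; partial cell is discarded

        point = nxt
        path.append(point.copy())
        arc_in_cell += step

        if arc_in_cell >= target - 1e-12:
            node_new = builder.add_node(point)
            cell_ids.append(
                builder.add_cell(node_prev, node_new, pending, target, params.tube_diameter_um)
            )
            septa.append((point.copy(), d.copy()))
            node_prev = node_new
            pending = []
            arc_in_cell = 0.0
            target = float(
                _lognormal_lengths(rng, params.mean_cell_length_um, params.cell_length_cv, 1)[0]
            )
        else:
            pending.append(point.copy())

    return np.asarray(path), septa, cell_ids


def _grow(params: SceneParams, rng: np.random.Generator) -> _Scene:
    grid = params.grid
    extent = grid.extent_um
    radius = params.tube_diameter_um / 2
    margin = radius + 0.5
    lo = np.array([margin, margin, min(margin, extent[2] / 4)])
    hi = extent - lo
    if params.n_hyphae > 0 and np.any(hi <= lo):
        raise GenerationError(
            f"volume {extent} µm cannot fit a hypha of diameter "
            f"{params.tube_diameter_um} µm"
        )

    builder = _SkeletonBuilder(grid)
    paths: list[np.ndarray] = []
    septa_all: list = []

    max_cells = 8
    for _ in range(params.n_hyphae):
        start = rng.uniform(lo, hi)
        phi = rng.uniform(0, 2 * np.pi)
        eta = rng.normal(0.0, 0.15)  # near-lateral initial course: the volume is thin
        direction = np.array([np.cos(phi), np.sin(phi), eta])
        direction /= np.linalg.norm(direction)

        path, septa, cell_ids = _walk_hypha(
            rng, builder, start, direction, params, lo, hi, max_cells
        )
        if len(path) > 1:
            paths.append(path)
            septa_all.extend(septa)

        # branches: one spawn decision per completed trunk cell, at its distal septum
        for i, cell_id in enumerate(cell_ids):
            if rng.uniform() >= params.branch_probability_per_cell:
                continue
            spawn_point, tangent = septa[i + 1]
            alpha = np.deg2rad(rng.uniform(30.0, 90.0))
            axis = _perpendicular(tangent, rng)
            branch_dir = _rotate(tangent, axis, alpha)
            bpath, bsepta, bcells = _walk_hypha(
                rng, builder, spawn_point, branch_dir, params, lo, hi, max_cells=2
            )
            if len(bcells) == 0:
                continue  # no room for a branch here; cell stays unmarked
            builder.mark_branching(cell_id)
            paths.append(bpath)
            septa_all.extend(bsepta[1:])  # spawn septum already drawn by the trunk

    skeleton = HyphalSkeleton(
        grid=grid,
        nodes=builder.nodes,
        cells=builder.cells,
        metadata={"generator": "hyphamorph.synthgen", "seed": params.seed},
    )
    truth = pd.DataFrame(
        builder.truth_rows, columns=["cell_id", "length_um", "diameter_um", "is_branching"]
    )
    return _Scene(skeleton=skeleton, truth=truth, paths=paths, septa=septa_all)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Points along a polyline at ~``step`` spacing (includes both ends)."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = float(seg_len.sum())
    if total == 0:
        return points[:1]
    n = max(int(np.ceil(total / step)), 1)
    targets = np.linspace(0.0, total, n + 1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seg) - 1)
    local = (targets - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    return points[idx] + local[:, None] * seg[idx]


def _patch_slices(
    grid: VoxelGrid, center_um: np.ndarray, radius_um: float
) -> Optional[tuple[tuple[slice, slice, slice], np.ndarray, np.ndarray, np.ndarray]]:
    spacing = grid.spacing
    lo_idx = np.maximum(np.ceil((center_um - radius_um) / spacing), 0).astype(int)
    hi_idx = np.minimum(
        np.floor((center_um + radius_um) / spacing), grid.counts - 1
    ).astype(int)
    if np.any(hi_idx < lo_idx):
        return None
    xs = np.arange(lo_idx[0], hi_idx[0] + 1) * spacing[0] - center_um[0]
    ys = np.arange(lo_idx[1], hi_idx[1] + 1) * spacing[1] - center_um[1]
    zs = np.arange(lo_idx[2], hi_idx[2] + 1) * spacing[2] - center_um[2]
    sl = (
        slice(lo_idx[2], hi_idx[2] + 1),
        slice(lo_idx[1], hi_idx[1] + 1),
        slice(lo_idx[0], hi_idx[0] + 1),
    )
    return sl, xs, ys, zs


def _render(scene: _Scene, params: SceneParams, rng: np.random.Generator) -> ImageStack:
    grid = params.grid
    radius = params.tube_diameter_um / 2
    sigma_wall = params.wall_thickness_um / FWHM_TO_SIGMA
    reach = radius + 3 * sigma_wall

    # distance of every voxel centre to the nearest centreline sample
    dist = np.full(grid.shape, np.inf, dtype=np.float32)
    for path in scene.paths:
        for point in _resample_polyline(path, RENDER_STEP_UM):
            patch = _patch_slices(grid, point, reach)
            if patch is None:
                continue
            sl, xs, ys, zs = patch
            d2 = (
                zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2
            )
            np.minimum(dist[sl], np.sqrt(d2, dtype=np.float32), out=dist[sl])

    field = np.full(grid.shape, params.background_intensity, dtype=np.float32)
    shell = np.isfinite(dist)
    field[shell] += params.wall_intensity * np.exp(
        -((dist[shell] - radius) ** 2) / (2 * sigma_wall**2)
    )
    del dist

    # septum disks: filled, perpendicular to the local axis
    for point, tangent in scene.septa:
        patch = _patch_slices(grid, point, radius + 3 * sigma_wall)
        if patch is None:
            continue
        sl, xs, ys, zs = patch
        px = xs[None, None, :]
        py = ys[None, :, None]
        pz = zs[:, None, None]
        axial = px * tangent[0] + py * tangent[1] + pz * tangent[2]
        r2 = px**2 + py**2 + pz**2 - axial**2
        disk = params.septum_intensity * np.exp(-(axial**2) / (2 * sigma_wall**2))
        field[sl] += np.where(r2 <= radius**2, disk, 0.0).astype(np.float32)

    field = ndimage.gaussian_filter(
        field,
        sigma=(
            params.psf_sigma_z_um / grid.dz,
            params.psf_sigma_xy_um / grid.dy,
            params.psf_sigma_xy_um / grid.dx,
        ),
        mode="nearest",
    )

    if params.noise_model == "gaussian":
        field = field + rng.normal(0.0, params.noise_param, size=field.shape).astype(
            np.float32
        )
        np.clip(field, 0, None, out=field)
    elif params.noise_model == "poisson":
        scale = params.noise_param
        field = (rng.poisson(np.clip(field, 0, None) * scale) / scale).astype(np.float32)

    return ImageStack(intensities=field, grid=grid)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def generate_skeleton(params: SceneParams) -> tuple[HyphalSkeleton, GroundTruth]:
    """Grow the hyphal skeleton only (no rendering) — cheap for statistics."""
    rng = np.random.default_rng(params.seed)
    scene = _grow(params, rng)
    return scene.skeleton, GroundTruth(skeleton=scene.skeleton, records=scene.truth)


def generate_scene(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    """Generate a full synthetic stack plus its ground truth.

    Deterministic: the same parameters (including ``seed``) yield a
    bit-identical stack and truth.
    """
    rng = np.random.default_rng(params.seed)
    scene = _grow(params, rng)
    stack = _render(scene, params, rng)
    return stack, GroundTruth(skeleton=scene.skeleton, records=scene.truth)


def tube_phantom(
    grid: VoxelGrid,
    diameter_um: float,
    length_um: float = 12.0,
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0),
    wall_thickness_um: float = 0.3,
    wall_intensity: float = 200.0,
    septum_intensity: float = 220.0,
    background_intensity: float = 10.0,
    psf_sigma_xy_um: float = 0.2,
    psf_sigma_z_um: float = 0.6,
    noise_model: str = "none",
    noise_param: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, HyphalSkeleton, GroundTruth]:
    """A single straight tube of known diameter, centred in the volume.

    The deterministic calibration target for width estimation: one cell
    between two septa, oriented along ``direction``, rendered by the same
    wall/septum/PSF model as full scenes.
    """
    params = SceneParams(
        grid=grid,
        n_hyphae=0,
        tube_diameter_um=diameter_um,
        wall_thickness_um=wall_thickness_um,
        wall_intensity=wall_intensity,
        septum_intensity=septum_intensity,
        background_intensity=background_intensity,
        psf_sigma_xy_um=psf_sigma_xy_um,
        psf_sigma_z_um=psf_sigma_z_um,
        noise_model=noise_model,
        noise_param=noise_param,
        seed=seed,
    )
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    center = grid.extent_um / 2
    a_um = center - d * length_um / 2
    b_um = center + d * length_um / 2
    for p in (a_um, b_um):
        if np.any(p < 0) or np.any(p > grid.extent_um):
            raise GenerationError("tube does not fit in the volume")

    builder = _SkeletonBuilder(grid)
    node_a = builder.add_node(a_um)
    node_b = builder.add_node(b_um)
    builder.add_cell(node_a, node_b, [], length_um, diameter_um)
    skeleton = HyphalSkeleton(
        grid=grid,
        nodes=builder.nodes,
        cells=builder.cells,
        metadata={"generator": "hyphamorph.synthgen.tube_phantom", "seed": seed},
    )
    truth = pd.DataFrame(
        builder.truth_rows, columns=["cell_id", "length_um", "diameter_um", "is_branching"]
    )
    scene = _Scene(
        skeleton=skeleton,
        truth=truth,
        paths=[np.vstack([a_um, b_um])],
        septa=[(a_um, d), (b_um, d)],
    )
    rng = np.random.default_rng(seed)
    stack = _render(scene, params, rng)
    return stack, skeleton, GroundTruth(skeleton=skeleton, records=truth)


def generate_benchmark_suite(
    out_dir,
    seeds: list[int],
    diameters: list[float],
    base_params: Optional[SceneParams] = None,
) -> list[tuple[Path, Path, Path]]:
    """Write one TIFF + annotation JSON + truth CSV triple per (seed, diameter).

    Deterministic per seed: re-running with the same arguments rewrites
    identical files. Returns the list of written triples.
    """
    if not seeds or not diameters:
        raise GenerationError("seeds and diameters must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if base_params is None:
        base_params = SceneParams()

    written = []
    for seed in seeds:
        for diameter in diameters:
            params = replace(base_params, seed=seed, tube_diameter_um=diameter)
            stack, truth = generate_scene(params)
            stem = f"scene_s{seed}_d{diameter:.2f}"
            tiff_path = out_dir / f"{stem}.tif"
            ann_path = out_dir / f"{stem}.json"
            truth_path = out_dir / f"{stem}_truth.csv"
            hio.write_stack(stack, tiff_path)
            hio.write_annotations(truth.skeleton, ann_path)
            truth.records.to_csv(truth_path, index=False, lineterminator="\n")
            written.append((tiff_path, ann_path, truth_path))
    return written
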