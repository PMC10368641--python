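"""Grid-based leaflet surfaces, thickness maps and midplane curvature maps.

The workflow follows the standard grid analysis of coarse-grained bilayers:
surface-marker beads (glycerol beads by default) of each leaflet are binned
onto a lateral xy grid, the per-cell mean z defines the leaflet surface, the
upper-minus-lower difference defines the local thickness, and the mean
curvature of the midplane height field quantifies bending.  Thickness is
averaged per frame and then over frames; cells occupied in fewer than half
of the frames (e.g. under a protein inclusion) are masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .trajio import BeadFrame, LeafletAssignment, Trajectory, assign_leaflets, select_beads

__all__ = [
    "GridSpec",
    "GridField",
    "ThicknessMap",
    "CurvatureMap",
    "grid_leaflet_surface",
    "thickness_map",
    "average_leaflet_surfaces",
    "midplane_height",
    "mean_curvature",
    "radial_profile",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular lateral grid over an (Lx, Ly) box.

    The requested cell size is rounded so an integer number of cells fits
    each axis, and the effective per-axis cell size re-derived.  Cells are
    half-open ``[x0, x0 + Δ)``: a bead exactly on a boundary belongs to the
    cell with the lower index, making membership deterministic.
    """

    cell_size: float
    box: tuple[float, float]
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.box[0] <= 0 or self.box[1] <= 0:
            raise ValueError("box lengths must be positive")

    @property
    def nx(self) -> int:
        return max(1, int(round(self.box[0] / self.cell_size)))

    @property
    def ny(self) -> int:
        return max(1, int(round(self.box[1] / self.cell_size)))

    @property
    def dx(self) -> float:
        return self.box[0] / self.nx

    @property
    def dy(self) -> float:
        return self.box[1] / self.ny

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i = np.floor((np.asarray(x) % self.box[0]) / self.dx).astype(int) % self.nx
        j = np.floor((np.asarray(y) % self.box[1]) / self.dy).astype(int) % self.ny
        return i, j


@dataclass
class GridField:
    """Per-cell values with validity mask and occupancy counts.

    ``values`` is (nx, ny); ``mask`` is True where the cell carries a value;
    masked cells hold NaN.
    """

    values: np.ndarray
    mask: np.ndarray
    occupancy: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        shape = (self.spec.nx, self.spec.ny)
        if self.values.shape != shape or self.mask.shape != shape:
            raise ValueError("array shape does not match grid spec")
        self.values = np.where(self.mask, self.values, np.nan)

    def congruent_with(self, other: "GridField") -> bool:
        return self.values.shape == other.values.shape and self.spec.box == other.spec.box


@dataclass
class ThicknessMap:
    """Time-averaged bilayer thickness (Å) per grid cell."""

    field: GridField
    n_frames: int


@dataclass
class CurvatureMap:
    """Mean curvature H (Å⁻¹) of the midplane, positive where the midplane
    bulges toward +z (the extracellular side in the usual membrane setup)."""

    field: GridField
    presmooth_sigma_cells: float


def _bin_mean_z(positions: np.ndarray, box: np.ndarray, spec: GridSpec
                ) -> tuple[np.ndarray, np.ndarray]:
    """(sum of z, count) per cell for the given bead positions."""
    i, j = spec.cell_of(positions[:, 0], positions[:, 1])
    flat = i * spec.ny + j
    sums = np.bincount(flat, weights=positions[:, 2], minlength=spec.nx * spec.ny)
    counts = np.bincount(flat, minlength=spec.nx * spec.ny)
    return sums.reshape(spec.nx, spec.ny), counts.reshape(spec.nx, spec.ny)


def grid_leaflet_surface(frame: BeadFrame, assignment: LeafletAssignment,
                         bead_selection: str | np.ndarray, spec: GridSpec
                         ) -> tuple[GridField, GridField]:
    """Per-leaflet surface: mean z of selected beads per lateral grid cell."""
    if isinstance(bead_selection, str):
        sel = select_beads(frame, bead_selection)
    else:
        sel = np.asarray(bead_selection, dtype=int)
    if len(sel) == 0:
        raise ValueError("empty bead selection")
    bead_labels = assignment.bead_labels(frame.n_beads)
    pos = frame.wrapped_lateral()
    out = []
    for label in ("upper", "lower"):
        idx = sel[bead_labels[sel] == label]
        sums, counts = _bin_mean_z(pos[idx], frame.box, spec)
        mask = counts > 0
        with np.errstate(invalid="ignore"):
            values = np.where(mask, sums / np.maximum(counts, 1), np.nan)
        out.append(GridField(values, mask, counts, spec))
    if not out[0].mask.any() and not out[1].mask.any():
        raise ValueError("no occupied grid cells in either leaflet")
    return out[0], out[1]


def _per_frame_assignments(traj: Trajectory, assignments, head_names, tail_names):
    if assignments is None:
        for frame in traj:
            yield frame, assign_leaflets(frame, head_names, tail_names)
    elif isinstance(assignments, LeafletAssignment):
        for frame in traj:
            yield frame, assignments
    else:
        for frame, a in zip(traj, assignments):
            yield frame, a


def thickness_map(traj: Trajectory, bead_selection: str = "bead GL1",
                  spec: GridSpec | None = None, assignments=None,
                  head_bead_names=("PO4",), tail_bead_names=("C1A", "C2A", "C1B", "C2B"),
                  min_frame_fraction: float = 0.5) -> ThicknessMap:
    """Time-averaged thickness map: per frame and cell, the upper-leaflet mean
    z minus the lower-leaflet mean z where both leaflets are occupied, then
    averaged over the frames in which the cell was defined.  Cells defined in
    fewer than ``min_frame_fraction`` of frames are masked.
    """
    if len(traj) < 1:
        raise ValueError("trajectory has no frames")
    if spec is None:
        spec = GridSpec(8.0, (traj.boxes[0][0], traj.boxes[0][1]))
    total = np.zeros((spec.nx, spec.ny))
    defined = np.zeros((spec.nx, spec.ny), dtype=int)
    occupancy = np.zeros((spec.nx, spec.ny), dtype=int)
    sel_idx = select_beads(traj.topology, bead_selection)
    for frame, assignment in _per_frame_assignments(
            traj, assignments, head_bead_names, tail_bead_names):
        upper, lower = grid_leaflet_surface(frame, assignment, sel_idx, spec)
        both = upper.mask & lower.mask
        total[both] += upper.values[both] - lower.values[both]
        defined += both
        occupancy += upper.occupancy + lower.occupancy
    mask = defined >= max(1, int(np.ceil(min_frame_fraction * len(traj))))
    if not mask.any():
        raise ValueError("no grid cell was ever defined in both leaflets")
    with np.errstate(invalid="ignore"):
        values = np.where(mask, total / np.maximum(defined, 1), np.nan)
    return ThicknessMap(GridField(values, mask, occupancy, spec), len(traj))


def average_leaflet_surfaces(traj: Trajectory, bead_selection: str = "bead GL1",
                             spec: GridSpec | None = None, assignments=None,
                             head_bead_names=("PO4",),
                             tail_bead_names=("C1A", "C2A", "C1B", "C2B"),
                             min_frame_fraction: float = 0.5
                             ) -> tuple[GridField, GridField]:
    """Frame-averaged upper and lower leaflet surfaces (input to curvature)."""
    if spec is None:
        spec = GridSpec(8.0, (traj.boxes[0][0], traj.boxes[0][1]))
    sel_idx = select_beads(traj.topology, bead_selection)
    sums = [np.zeros((spec.nx, spec.ny)) for _ in range(2)]
    defined = [np.zeros((spec.nx, spec.ny), dtype=int) for _ in range(2)]
    occ = [np.zeros((spec.nx, spec.ny), dtype=int) for _ in range(2)]
    for frame, assignment in _per_frame_assignments(
            traj, assignments, head_bead_names, tail_bead_names):
        for k, f in enumerate(grid_leaflet_surface(frame, assignment, sel_idx, spec)):
            sums[k][f.mask] += f.values[f.mask]
            defined[k] += f.mask
            occ[k] += f.occupancy
    out = []
    need = max(1, int(np.ceil(min_frame_fraction * len(traj))))
    for k in range(2):
        mask = defined[k] >= need
        with np.errstate(invalid="ignore"):
            values = np.where(mask, sums[k] / np.maximum(defined[k], 1), np.nan)
        out.append(GridField(values, mask, occ[k], spec))
    return out[0], out[1]


def midplane_height(upper: GridField, lower: GridField) -> GridField:
    """Cellwise (upper + lower)/2 where both leaflet surfaces are defined."""
    if not upper.congruent_with(lower):
        raise ValueError("leaflet grids are not congruent")
    mask = upper.mask & lower.mask
    with np.errstate(invalid="ignore"):
        values = np.where(mask, 0.5 * (upper.values + lower.values), np.nan)
    return GridField(values, mask, upper.occupancy + lower.occupancy, upper.spec)


def _smooth_masked(h: np.ndarray, mask: np.ndarray, sigma: float, mode: str) -> np.ndarray:
    """Normalized-convolution Gaussian smoothing that ignores masked cells."""
    filled = np.where(mask, h, 0.0)
    w = mask.astype(float)
    num = ndimage.gaussian_filter(filled, sigma, mode=mode)
    den = ndimage.gaussian_filter(w, sigma, mode=mode)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def mean_curvature(height: GridField, presmooth_sigma_cells: float = 1.0) -> CurvatureMap:
    """Mean curvature H of the height field by the Monge-patch formula.

    Derivatives are central finite differences (periodic wrap on periodic
    grids, one-sided edges otherwise); the height grid is optionally
    pre-smoothed with a Gaussian of the given width in cells, using
    normalized convolution so masked cells do not bleed in.  Sign convention:
    H > 0 where the surface bulges toward +z, so the membrane dimple that
    forms around a docking site reads as negative curvature.
    """
    spec = height.spec
    if spec.nx < 3 or spec.ny < 3:
        raise ValueError("grid too small for curvature (need at least 3x3)")
    mode = "wrap" if spec.periodic else "nearest"
    h = np.where(height.mask, height.values, 0.0)
    if presmooth_sigma_cells > 0:
        h = _smooth_masked(height.values, height.mask, presmooth_sigma_cells, mode)
    else:
        h = _smooth_masked(height.values, height.mask, 0.0, mode) if not height.mask.all() else h

    dx, dy = spec.dx, spec.dy
    if spec.periodic:
        def d1(a, axis, d):
            return (np.roll(a, -1, axis) - np.roll(a, 1, axis)) / (2 * d)

        def d2(a, axis, d):
            return (np.roll(a, -1, axis) - 2 * a + np.roll(a, 1, axis)) / (d * d)

        h_x, h_y = d1(h, 0, dx), d1(h, 1, dy)
        h_xx, h_yy = d2(h, 0, dx), d2(h, 1, dy)
        h_xy = d1(h_x, 1, dy)
    else:
        h_x = np.gradient(h, dx, axis=0)
        h_y = np.gradient(h, dy, axis=1)
        h_xx = np.gradient(h_x, dx, axis=0)
        h_yy = np.gradient(h_y, dy, axis=1)
        h_xy = np.gradient(h_x, dy, axis=1)

    num = h_xx * (1 + h_y ** 2) - 2 * h_x * h_y * h_xy + h_yy * (1 + h_x ** 2)
    den = 2.0 * (1 + h_x ** 2 + h_y ** 2) ** 1.5
    H = -num / den  # positive = bulge toward +z

    # only cells with a fully unmasked 3x3 neighborhood are trustworthy
    valid = ndimage.minimum_filter(height.mask.astype(np.uint8), size=3, mode=mode) == 1
    return CurvatureMap(GridField(np.where(valid, H, np.nan), valid,
                                  height.occupancy, spec), presmooth_sigma_cells)


def radial_profile(field: GridField, center: tuple[float, float],
                   bin_width: float) -> pd.DataFrame:
    """Azimuthal average of a grid field around a center point.

    Distances are periodic minimum-image; the center is wrapped into the box
    first, so any representative of the periodic image gives the same
    profile.  Returns a table of (bin center, mean value, n cells); empty
    bins are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if not field.mask.any():
        raise ValueError("field has no unmasked cells")
    spec = field.spec
    cx, cy = center[0] % spec.box[0], center[1] % spec.box[1]
    X, Y = np.meshgrid(spec.x_centers(), spec.y_centers(), indexing="ij")
    dx = X - cx
    dy = Y - cy
    dx -= spec.box[0] * np.round(dx / spec.box[0])
    dy -= spec.box[1] * np.round(dy / spec.box[1])
    r = np.sqrt(dx * dx + dy * dy)[field.mask]
    v = field.values[field.mask]
    bins = np.floor(r / bin_width).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        rows.append(((b + 0.5) * bin_width, float(v[sel].mean()), int(sel.sum())))
    return pd.DataFrame(rows, columns=["distance", "mean_value", "n_cells"])
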