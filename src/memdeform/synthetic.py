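"""Synthetic bead-bilayer trajectories and density slabs with known ground truth.

The generator emulates the geometry of a coarse-grained bacterial model
membrane — two leaflets of three lipid species at a 70:25:5 molar ratio,
roughly 325 lipids per leaflet in a ~15 × 15 nm lateral box — without any
force field or dynamics.  Leaflet surfaces follow prescribed midplane-height
and thickness fields, every bead receives independent isotropic Gaussian
positional noise per frame, and an optional rigid, tilted helix bundle
excludes lipids from a cylindrical footprint.  Because the deformation
fields, tilt angle and species counts are known exactly, every downstream
analysis stage can be tested as a parameter-recovery problem.

All lengths are Å; fields are evaluated with periodic lateral wrapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .density import DensityMap
from .trajio import BeadFrame, Trajectory

__all__ = [
    "DeformationField",
    "BilayerSpec",
    "InclusionSpec",
    "GroundTruth",
    "make_deformation_field",
    "largest_remainder_counts",
    "generate_trajectory",
    "generate_density_slab",
    "save_ground_truth",
    "load_ground_truth",
]

# fixed intra-lipid bead geometry (Å offsets from the glycerol bead, away
# from / toward the bilayer midplane)
HEAD_OFFSET = 4.5
TAIL_OFFSETS = (4.5, 9.0)
HEAD_BEAD = "PO4"
GLYCEROL_BEAD = "GL1"
TAIL_BEADS = ("C1A", "C2A")


@dataclass(frozen=True)
class DeformationField:
    """Scalar field over the periodic lateral plane.

    Kinds: ``flat`` (constant = amplitude), ``sinusoid``
    (A·sin(2π u / wavelength) with u along ``axis``), ``radial_gaussian``
    (A·exp(−d²/(2·width²)) with d the minimum-image distance to ``center``).
    """

    kind: str
    amplitude: float = 0.0
    wavelength: float | None = None
    width: float | None = None
    center: tuple[float, float] = (0.0, 0.0)
    axis: str = "x"

    def evaluate(self, x, y, box: Sequence[float] | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "flat":
            return np.broadcast_to(np.float64(self.amplitude), np.broadcast_shapes(x.shape, y.shape)).copy()
        if self.kind == "sinusoid":
            u = x if self.axis == "x" else y
            return self.amplitude * np.sin(2.0 * np.pi * u / self.wavelength)
        if self.kind == "radial_gaussian":
            dx = x - self.center[0]
            dy = y - self.center[1]
            if box is not None:
                dx = dx - box[0] * np.round(dx / box[0])
                dy = dy - box[1] * np.round(dy / box[1])
            d2 = dx * dx + dy * dy
            return self.amplitude * np.exp(-d2 / (2.0 * self.width ** 2))
        raise ValueError(f"unknown deformation field kind: {self.kind!r}")

    __call__ = evaluate


def make_deformation_field(kind: str, **parameters) -> DeformationField:
    """Build a :class:`DeformationField`, validating kind and parameters."""
    known = {"flat", "sinusoid", "radial_gaussian"}
    if kind not in known:
        raise ValueError(f"unknown deformation field kind: {kind!r} (known: {sorted(known)})")
    if kind == "sinusoid" and parameters.get("wavelength") is None:
        raise ValueError("sinusoid field requires a wavelength")
    if kind == "radial_gaussian" and parameters.get("width") is None:
        raise ValueError("radial_gaussian field requires a width")
    allowed = {"amplitude", "wavelength", "width", "center", "axis"}
    unknown = set(parameters) - allowed
    if unknown:
        raise ValueError(f"unknown field parameters: {sorted(unknown)}")
    if "center" in parameters:
        parameters["center"] = tuple(parameters["center"])
    return DeformationField(kind=kind, **parameters)


_FLAT = DeformationField("flat", 0.0)


@dataclass(frozen=True)
class BilayerSpec:
    """Geometry and statistics of a synthetic two-leaflet bead bilayer."""

    box_x: float = 150.0
    box_y: float = 150.0
    n_lipids_per_leaflet: int = 325
    species_fractions: tuple[tuple[str, float], ...] = (
        ("POPE", 0.70), ("POPG", 0.25), ("CDL", 0.05))
    base_thickness_t0: float = 38.0
    height_field: DeformationField = _FLAT
    thickness_field: DeformationField = _FLAT
    noise_sigma: float = 0.0
    n_frames: int = 1
    seed: int = 0
    box_z: float = 150.0

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.species_fractions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species fractions sum to {total}, not 1")
        if self.n_lipids_per_leaflet <= 0:
            raise ValueError("n_lipids_per_leaflet must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.box_x <= 0 or self.box_y <= 0:
            raise ValueError("box lengths must be positive")


@dataclass(frozen=True)
class InclusionSpec:
    """A rigid, tilted helix bundle that excludes lipids from a cylinder.

    The helix is a straight run of backbone beads centred on ``anchor``,
    tilted ``prescribed_tilt`` degrees from +z at the given azimuth, with one
    residue id per bead taken from ``residue_id_range`` (inclusive).  Optional
    per-frame Gaussian jitter on the tilt angle supports tilt-recovery tests;
    the helix has no internal motion.
    """

    radius: float = 15.0
    helix_length: float = 43.5
    n_backbone_beads: int = 29
    prescribed_tilt: float = 0.0
    azimuth: float = 0.0
    anchor: tuple[float, float, float] = (75.0, 75.0, 0.0)
    residue_id_range: tuple[int, int] = (106, 134)
    tilt_jitter_sigma: float = 0.0
    chain: str = "S"
    resname: str = "HEL"
    bead_name: str = "BB"

    def __post_init__(self) -> None:
        if not (0.0 <= self.prescribed_tilt <= 90.0):
            raise ValueError("prescribed_tilt must be in [0, 90] degrees")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        lo, hi = self.residue_id_range
        if hi - lo + 1 != self.n_backbone_beads:
            raise ValueError("residue_id_range must supply one id per backbone bead")
        if self.n_backbone_beads < 2:
            raise ValueError("helix needs at least two beads")


@dataclass
class GroundTruth:
    """What the generator prescribed, for recovery tests."""

    height_at: Callable[[np.ndarray, np.ndarray], np.ndarray]
    thickness_at: Callable[[np.ndarray, np.ndarray], np.ndarray]
    species_counts: dict[str, int]
    box: np.ndarray
    base_thickness_t0: float
    noise_sigma: float
    n_frames: int
    seed: int
    prescribed_tilt: float | None = None
    inclusion_radius: float | None = None
    inclusion_center: tuple[float, float] | None = None
    height_field: DeformationField | None = None
    thickness_field: DeformationField | None = None


def largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Apportion ``n`` into integer counts by largest-remainder rounding.

    Deterministic and exactly total-preserving; ties broken by lower index.
    """
    quotas = [n * f for f in fractions]
    counts = [math.floor(q) for q in quotas]
    shortfall = n - sum(counts)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:shortfall]:
        counts[i] += 1
    return counts


def _hex_lattice_sites(Lx: float, Ly: float, n_min: int, rng: np.random.Generator,
                       jitter_frac: float = 0.15) -> np.ndarray:
    """Jittered hexagonal lattice with at least ``n_min`` sites in the box."""
    a = math.sqrt(2.0 * Lx * Ly / (math.sqrt(3.0) * n_min))
    nx = max(2, math.ceil(Lx / a))
    ny = max(2, math.ceil(Ly / (a * math.sqrt(3.0) / 2.0)))
    while nx * ny < n_min:
        nx += 1
    dx, dy = Lx / nx, Ly / ny
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = (ix + 0.25 + 0.5 * (iy % 2)) * dx
    y = (iy + 0.5) * dy
    sites = np.column_stack([x.ravel(), y.ravel()])
    sites += rng.normal(0.0, jitter_frac * min(dx, dy), size=sites.shape)
    sites[:, 0] %= Lx
    sites[:, 1] %= Ly
    return sites


def _helix_positions(inc: InclusionSpec, tilt_deg: float) -> np.ndarray:
    t = math.radians(tilt_deg)
    a = math.radians(inc.azimuth)
    d = np.array([math.sin(t) * math.cos(a), math.sin(t) * math.sin(a), math.cos(t)])
    n = inc.n_backbone_beads
    s = (np.arange(n) - (n - 1) / 2.0) * (inc.helix_length / (n - 1))
    return np.asarray(inc.anchor, dtype=float)[None, :] + s[:, None] * d[None, :]


def generate_trajectory(spec: BilayerSpec, inclusion: InclusionSpec | None = None,
                        seed: int | None = None) -> tuple[Trajectory, GroundTruth]:
    """Generate a bead-bilayer trajectory with prescribed deformation fields.

    Each lipid carries one head bead above its glycerol bead (away from the
    midplane), the glycerol bead on the leaflet surface, and two tail beads
    toward the midplane, so head-to-tail orientation encodes the leaflet.
    Upper-leaflet glycerol beads sit at ``z = h(x,y) + t(x,y)/2`` (lower at
    ``h − t/2``) plus per-frame isotropic Gaussian noise.  Lipid lateral
    positions come from a jittered hexagonal lattice with rejection inside
    the inclusion cylinder; the helix is rebuilt per frame only when tilt
    jitter is requested.  A fixed seed gives bitwise-identical output.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    Lx, Ly = spec.box_x, spec.box_y
    box = np.array([Lx, Ly, spec.box_z])

    if inclusion is not None:
        if 2.0 * inclusion.radius >= min(Lx, Ly):
            raise ValueError("inclusion diameter exceeds the lateral box")
        cx, cy = inclusion.anchor[0], inclusion.anchor[1]

    names = [s for s, _ in spec.species_fractions]
    counts = largest_remainder_counts(spec.n_lipids_per_leaflet,
                                      [f for _, f in spec.species_fractions])

    def h_at(x, y):
        return spec.height_field(x, y, box=(Lx, Ly))

    def t_at(x, y):
        return spec.base_thickness_t0 + spec.thickness_field(x, y, box=(Lx, Ly))

    # lateral sites per leaflet (fixed across frames)
    excl_area = math.pi * inclusion.radius ** 2 if inclusion is not None else 0.0
    usable = max(1e-6, 1.0 - excl_area / (Lx * Ly))
    n_target = math.ceil(spec.n_lipids_per_leaflet / usable * 1.15) + 8
    leaflet_xy = []
    for _leaflet in ("upper", "lower"):
        sites = _hex_lattice_sites(Lx, Ly, n_target, rng)
        if inclusion is not None:
            dx = sites[:, 0] - cx
            dy = sites[:, 1] - cy
            dx -= Lx * np.round(dx / Lx)
            dy -= Ly * np.round(dy / Ly)
            sites = sites[dx * dx + dy * dy > inclusion.radius ** 2]
        if len(sites) < spec.n_lipids_per_leaflet:
            raise ValueError("inclusion too large: not enough lateral sites for lipids")
        chosen = rng.choice(len(sites), size=spec.n_lipids_per_leaflet, replace=False)
        leaflet_xy.append(sites[np.sort(chosen)])

    # species labels per leaflet, shuffled deterministically
    species = np.repeat(names, counts)
    labels_per_leaflet = [rng.permutation(species), rng.permutation(species)]

    # static topology arrays
    beads_per_lipid = 2 + len(TAIL_OFFSETS)
    chains_l, resids_l, resnames_l, names_l = [], [], [], []
    base_positions = []
    resid = 0
    for leaflet, sign in (("upper", +1.0), ("lower", -1.0)):
        xy = leaflet_xy[0 if leaflet == "upper" else 1]
        labels = labels_per_leaflet[0 if leaflet == "upper" else 1]
        gl_z = h_at(xy[:, 0], xy[:, 1]) + sign * 0.5 * t_at(xy[:, 0], xy[:, 1])
        for k in range(len(xy)):
            resid += 1
            zs = [gl_z[k] + sign * HEAD_OFFSET, gl_z[k]] + \
                 [gl_z[k] - sign * off for off in TAIL_OFFSETS]
            for bead, z in zip((HEAD_BEAD, GLYCEROL_BEAD) + TAIL_BEADS, zs):
                chains_l.append("M")
                resids_l.append(resid)
                resnames_l.append(str(labels[k]))
                names_l.append(bead)
                base_positions.append((xy[k, 0], xy[k, 1], z))
    n_lipid_beads = len(base_positions)
    assert n_lipid_beads == 2 * spec.n_lipids_per_leaflet * beads_per_lipid

    if inclusion is not None:
        lo = inclusion.residue_id_range[0]
        for i in range(inclusion.n_backbone_beads):
            chains_l.append(inclusion.chain)
            resids_l.append(lo + i)
            resnames_l.append(inclusion.resname)
            names_l.append(inclusion.bead_name)
        base_helix = _helix_positions(inclusion, inclusion.prescribed_tilt)
        base_positions.extend(map(tuple, base_helix))

    base = np.array(base_positions, dtype=float)
    topology = BeadFrame(
        chains=np.array(chains_l, dtype=object),
        resids=np.array(resids_l, dtype=int),
        resnames=np.array(resnames_l, dtype=object),
        names=np.array(names_l, dtype=object),
        positions=base.copy(),
        box=box.copy(),
    )

    coords = np.empty((spec.n_frames, len(base), 3))
    for f in range(spec.n_frames):
        frame = base.copy()
        if spec.noise_sigma > 0:
            frame[:n_lipid_beads] += rng.normal(
                0.0, spec.noise_sigma, size=(n_lipid_beads, 3))
        if inclusion is not None and inclusion.tilt_jitter_sigma > 0:
            tilt_f = inclusion.prescribed_tilt + rng.normal(0.0, inclusion.tilt_jitter_sigma)
            frame[n_lipid_beads:] = _helix_positions(inclusion, tilt_f)
        coords[f] = frame
    boxes = np.tile(box, (spec.n_frames, 1))

    truth = GroundTruth(
        height_at=h_at,
        thickness_at=t_at,
        species_counts=dict(zip(names, counts)),
        box=box.copy(),
        base_thickness_t0=spec.base_thickness_t0,
        noise_sigma=spec.noise_sigma,
        n_frames=spec.n_frames,
        seed=seed,
        prescribed_tilt=inclusion.prescribed_tilt if inclusion is not None else None,
        inclusion_radius=inclusion.radius if inclusion is not None else None,
        inclusion_center=(cx, cy) if inclusion is not None else None,
        height_field=spec.height_field,
        thickness_field=spec.thickness_field,
    )
    return Trajectory(topology, coords, boxes), truth


# ---------------------------------------------------------------------------
# Density slabs


def generate_density_slab(width: float, voxel: float = 1.0,
                          smoothing_sigma: float = 0.0, noise_sigma: float = 0.0,
                          seed: int = 0, lateral_extent: float = 48.0,
                          z_extent: float | None = None,
                          center_z: float | None = None) -> DensityMap:
    """Synthetic density: value 1 inside a z-slab of the given width, 0 outside.

    Optionally Gaussian-smoothed (σ in Å) and corrupted with voxel noise —
    a controllable stand-in for a membrane slab in a cryo-EM reconstruction.
    """
    from scipy import ndimage

    if width <= 0 or voxel <= 0:
        raise ValueError("width and voxel size must be positive")
    if width < voxel:
        raise ValueError(f"slab width {width} Å smaller than one voxel ({voxel} Å)")
    if z_extent is None:
        z_extent = max(3.0 * width, width + 40.0)
    nxy = max(4, int(round(lateral_extent / voxel)))
    nz = max(8, int(round(z_extent / voxel)))
    if center_z is None:
        center_z = 0.5 * nz * voxel
    z = (np.arange(nz) + 0.5) * voxel  # voxel centres, origin at the box corner
    inside = np.abs(z - center_z) < 0.5 * width
    data = np.zeros((nxy, nxy, nz))
    data[:, :, inside] = 1.0
    if smoothing_sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=smoothing_sigma / voxel, mode="nearest")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sigma, size=data.shape)
    # voxel centres at origin + i*spacing  =>  origin offset of half a voxel
    return DensityMap(data, np.full(3, voxel), origin=np.full(3, 0.5 * voxel))


# ---------------------------------------------------------------------------
# Ground-truth sidecar (plain-text key=value)


def _field_items(prefix: str, f: DeformationField | None) -> list[str]:
    if f is None:
        return []
    items = [f"{prefix}.kind={f.kind}", f"{prefix}.amplitude={f.amplitude!r}"]
    if f.wavelength is not None:
        items.append(f"{prefix}.wavelength={f.wavelength!r}")
    if f.width is not None:
        items.append(f"{prefix}.width={f.width!r}")
    items.append(f"{prefix}.center={f.center[0]!r},{f.center[1]!r}")
    items.append(f"{prefix}.axis={f.axis}")
    return items


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    lines = [
        f"box={float(truth.box[0])!r},{float(truth.box[1])!r},{float(truth.box[2])!r}",
        f"base_thickness_t0={truth.base_thickness_t0!r}",
        f"noise_sigma={truth.noise_sigma!r}",
        f"n_frames={truth.n_frames}",
        f"seed={truth.seed}",
    ]
    for name, count in truth.species_counts.items():
        lines.append(f"count.{name}={count}")
    if truth.prescribed_tilt is not None:
        lines.append(f"prescribed_tilt={truth.prescribed_tilt!r}")
    if truth.inclusion_radius is not None:
        lines.append(f"inclusion_radius={truth.inclusion_radius!r}")
        lines.append(f"inclusion_center={float(truth.inclusion_center[0])!r},{float(truth.inclusion_center[1])!r}")
    lines += _field_items("height_field", truth.height_field)
    lines += _field_items("thickness_field", truth.thickness_field)
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_field(prefix: str, kv: dict[str, str]) -> DeformationField | None:
    if f"{prefix}.kind" not in kv:
        return None
    params: dict = {"amplitude": float(kv[f"{prefix}.amplitude"])}
    if f"{prefix}.wavelength" in kv:
        params["wavelength"] = float(kv[f"{prefix}.wavelength"])
    if f"{prefix}.width" in kv:
        params["width"] = float(kv[f"{prefix}.width"])
    cx, cy = kv[f"{prefix}.center"].split(",")
    params["center"] = (float(cx), float(cy))
    params["axis"] = kv[f"{prefix}.axis"]
    return make_deformation_field(kv[f"{prefix}.kind"], **params)


def load_ground_truth(path: str | Path) -> GroundTruth:
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip() and "=" in line:
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
    box = np.array([float(v) for v in kv["box"].split(",")])
    hf = _parse_field("height_field", kv) or _FLAT
    tf = _parse_field("thickness_field", kv) or _FLAT
    t0 = float(kv["base_thickness_t0"])
    counts = {k.split(".", 1)[1]: int(v) for k, v in kv.items() if k.startswith("count.")}
    center = None
    if "inclusion_center" in kv:
        cx, cy = kv["inclusion_center"].split(",")
        center = (float(cx), float(cy))
    return GroundTruth(
        height_at=lambda x, y: hf(x, y, box=(box[0], box[1])),
        thickness_at=lambda x, y: t0 + tf(x, y, box=(box[0], box[1])),
        species_counts=counts,
        box=box,
        base_thickness_t0=t0,
        noise_sigma=float(kv["noise_sigma"]),
        n_frames=int(kv["n_frames"]),
        seed=int(kv["seed"]),
        prescribed_tilt=float(kv["prescribed_tilt"]) if "prescribed_tilt" in kv else None,
        inclusion_radius=float(kv["inclusion_radius"]) if "inclusion_radius" in kv else None,
        inclusion_center=center,
        height_field=hf,
        thickness_field=tf,
    )
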