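"""Helix tilt-angle statistics and structure superposition metrics.

Tilt is defined against the membrane normal, approximated by the simulation
box z-axis: the helix axis is the first principal component of its backbone
positions (sign fixed to point N→C) and the reported angle is folded into
[0°, 90°], so an axis and its negation give the same tilt.  Superposition
uses the closed-form Kabsch least-squares rotation with the proper-rotation
correction, and displacement metrics compare two conformations after
aligning on a common rigid selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import BeadFrame, Trajectory, select_beads

__all__ = [
    "HelixSelectionSpec",
    "TiltSeries",
    "Superposition",
    "helix_axis",
    "tilt_angle",
    "tilt_series",
    "superpose_rmsd",
    "pair_by_identity",
    "displacement_metrics",
]


@dataclass(frozen=True)
class HelixSelectionSpec:
    """Which beads define the helix: an inclusive residue range on one chain
    (chain optional for formats that do not store one) and a backbone
    bead/atom name."""

    resid_range: tuple[int, int]
    backbone_name: str = "BB"
    chain: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.resid_range
        if hi < lo:
            raise ValueError("empty residue range")

    def expression(self) -> str:
        lo, hi = self.resid_range
        expr = f"resid {lo}-{hi} and name {self.backbone_name}"
        if self.chain:
            expr += f" and chain {self.chain}"
        return expr


@dataclass
class TiltSeries:
    """Per-frame tilt angles (degrees from +z, in [0, 90]) with summaries."""

    angles: np.ndarray
    n_blocks: int = 5

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any(self.angles < 0) or np.any(self.angles > 90):
            raise ValueError("tilt angles must lie in [0, 90] degrees")

    @property
    def mean(self) -> float:
        return float(self.angles.mean())

    @property
    def std(self) -> float:
        return float(self.angles.std(ddof=1)) if len(self.angles) > 1 else 0.0

    @property
    def block_sem(self) -> float:
        """Standard error of the mean from block averages (default 5 blocks),
        the standard estimator for correlated trajectory data."""
        k = min(self.n_blocks, len(self.angles))
        if k < 2:
            return float("nan")
        usable = (len(self.angles) // k) * k
        means = self.angles[:usable].reshape(k, -1).mean(axis=1)
        return float(means.std(ddof=1) / np.sqrt(k))


@dataclass
class Superposition:
    """Optimal rigid superposition: x' = R·x + t, with residual rmsd (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def helix_axis(positions: np.ndarray) -> np.ndarray:
    """Unit axis of a helix as the first principal component of its backbone.

    Positions must be ordered N→C; the sign is fixed so the axis points from
    the N-half centroid toward the C-half centroid.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
        raise ValueError("need at least 3 ordered positions")
    centered = p - p.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-10:
        raise ValueError("degenerate helix: all points coincide")
    axis = vt[0]
    half = len(p) // 2
    direction = p[half:].mean(axis=0) - p[:half].mean(axis=0)
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def tilt_angle(axis: np.ndarray) -> float:
    """Angle (degrees) between a vector and the +z membrane normal, folded
    into [0, 90] so that v and −v give the same tilt."""
    v = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero vector has no direction")
    cos = abs(v[2]) / norm
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def tilt_series(traj: Trajectory, spec: HelixSelectionSpec, n_blocks: int = 5) -> TiltSeries:
    """Per-frame helix tilt against the box z-axis over a trajectory."""
    sel = select_beads(traj.topology, spec.expression())
    if len(sel) < 3:
        raise ValueError(f"helix selection {spec.expression()!r} matched "
                         f"{len(sel)} beads; need at least 3")
    order = np.argsort(traj.topology.resids[sel], kind="stable")
    sel = sel[order]  # N→C by ascending residue id
    angles = np.empty(len(traj))
    for f in range(len(traj)):
        angles[f] = tilt_angle(helix_axis(traj.coordinates[f, sel]))
    return TiltSeries(angles, n_blocks=n_blocks)


def superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Kabsch least-squares superposition of paired coordinate sets.

    Returns the proper rotation (det +1) and translation minimizing the rmsd
    of mobile onto reference.  Nearly collinear point sets are flagged
    ``degenerate`` (the rotation about the line is then arbitrary).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    n = len(P)
    if n < 3:
        raise ValueError("need at least 3 atom pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    # collinear inputs leave the second singular value ~0
    scale = S[0] if S[0] > 0 else 1.0
    degenerate = bool(S[1] / scale < 1e-8)
    return Superposition(R, t, rmsd, n, degenerate)


def pair_by_identity(frame_a: BeadFrame, frame_b: BeadFrame,
                     selection: str | None = None
                     ) -> tuple[np.ndarray, np.ndarray, list]:
    """Pair beads between two models by (chain, residue id, name) identity.

    Returns coordinates of A and B over the shared keys (sorted) plus the
    keys themselves; unmatched beads are dropped (models routinely differ in
    which residues are resolved).
    """
    def keyed(frame):
        idx = select_beads(frame, selection) if selection else np.arange(frame.n_beads)
        return {(str(frame.chains[i]), int(frame.resids[i]), str(frame.names[i])): i
                for i in idx}

    ka, kb = keyed(frame_a), keyed(frame_b)
    shared = sorted(set(ka) & set(kb))
    if not shared:
        raise ValueError("no common (chain, resid, name) pairs between models")
    ia = np.array([ka[k] for k in shared])
    ib = np.array([kb[k] for k in shared])
    return frame_a.positions[ia], frame_b.positions[ib], shared


def displacement_metrics(model_open: BeadFrame, model_closed: BeadFrame,
                         align_selection: str, probe_selection: str,
                         probe_selection_2: str | None = None) -> dict:
    """Conformational displacement of a probe region between two models.

    The closed model is superposed onto the open model over
    ``align_selection``; the report then contains the probe centroid
    displacement (Å), its z-component, and the mean per-residue displacement.
    With a second probe selection the change in inter-centroid separation is
    added (positive = the two probes moved toward each other).
    """
    a_align, b_align, _ = pair_by_identity(model_open, model_closed, align_selection)
    sup = superpose_rmsd(b_align, a_align)  # move closed onto open

    a_probe, b_probe, keys = pair_by_identity(model_open, model_closed, probe_selection)
    if len(keys) == 0:
        raise ValueError("empty probe selection")
    b_moved = sup.apply(b_probe)
    disp_vec = b_moved.mean(axis=0) - a_probe.mean(axis=0)

    # mean over residues of the residue-centroid displacement magnitude
    resids = np.array([k[1] for k in keys])
    per_res = []
    for r in np.unique(resids):
        m = resids == r
        per_res.append(np.linalg.norm(b_moved[m].mean(axis=0) - a_probe[m].mean(axis=0)))

    out = {
        "alignment_rmsd": sup.rmsd,
        "centroid_displacement": float(np.linalg.norm(disp_vec)),
        "centroid_displacement_z": float(disp_vec[2]),
        "per_residue_mean": float(np.mean(per_res)),
    }
    if probe_selection_2 is not None:
        a2, b2, _ = pair_by_identity(model_open, model_closed, probe_selection_2)
        b2_moved = sup.apply(b2)
        sep_open = np.linalg.norm(a_probe.mean(axis=0) - a2.mean(axis=0))
        sep_closed = np.linalg.norm(b_moved.mean(axis=0) - b2_moved.mean(axis=0))
        out["separation_open"] = float(sep_open)
        out["separation_closed"] = float(sep_closed)
        out["separation_change"] = float(sep_open - sep_closed)
    return out
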