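"""Bead-system I/O, selections and leaflet assignment.

Coordinates are held in ångström throughout the package; GRO files (nm) are
converted on read and write.  File parsing is delegated to MDAnalysis, which
handles the fixed-column GRO/PDB dialects and the XTC/TRR/DCD trajectory
formats; this module wraps it behind plain numpy containers so the analysis
code never touches a Universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BeadFrame",
    "Trajectory",
    "LeafletAssignment",
    "ParseError",
    "SelectionError",
    "read_coordinates",
    "read_trajectory",
    "select_beads",
    "assign_leaflets",
    "write_gro",
    "write_trajectory",
]


class ParseError(ValueError):
    """A coordinate or trajectory file could not be parsed."""


class SelectionError(ValueError):
    """A selection expression is syntactically invalid."""


@dataclass
class BeadFrame:
    """One time point of a bead system.

    Arrays are parallel over beads; ``box`` is the orthorhombic cell
    (Lx, Ly, Lz) in Å.
    """

    chains: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    names: np.ndarray
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        for arr in (self.chains, self.resids, self.resnames, self.names):
            if len(arr) != n:
                raise ValueError("bead attribute arrays must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "BeadFrame":
        return BeadFrame(
            self.chains.copy(),
            self.resids.copy(),
            self.resnames.copy(),
            self.names.copy(),
            self.positions.copy(),
            self.box.copy(),
        )

    def wrapped_lateral(self) -> np.ndarray:
        """Positions with x, y wrapped into the primary box; z untouched.

        The membrane is continuous through the lateral periodic boundaries,
        so analyses wrap laterally only — wrapping z would split leaflets.
        """
        pos = self.positions.copy()
        pos[:, 0] %= self.box[0]
        pos[:, 1] %= self.box[1]
        return pos

    def residue_segments(self) -> list[np.ndarray]:
        """Index arrays of consecutive beads sharing (chain, resname, resid)."""
        if self.n_beads == 0:
            return []
        keys = list(zip(self.chains, self.resnames, self.resids))
        segments: list[np.ndarray] = []
        start = 0
        for i in range(1, self.n_beads + 1):
            if i == self.n_beads or keys[i] != keys[start]:
                segments.append(np.arange(start, i))
                start = i
        return segments


@dataclass
class Trajectory:
    """In-memory trajectory: static labels plus per-frame coordinates/boxes."""

    topology: BeadFrame
    coordinates: np.ndarray  # (n_frames, n_beads, 3) Å
    boxes: np.ndarray  # (n_frames, 3) Å

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[1] != self.topology.n_beads:
            raise ValueError("coordinate array must be (n_frames, n_beads, 3)")
        if self.boxes.shape != (len(self.coordinates), 3):
            raise ValueError("one box per frame required")

    def __len__(self) -> int:
        return len(self.coordinates)

    def __getitem__(self, i: int) -> BeadFrame:
        top = self.topology
        return BeadFrame(top.chains, top.resids, top.resnames, top.names,
                         self.coordinates[i], self.boxes[i])

    def __iter__(self) -> Iterator[BeadFrame]:
        for i in range(len(self)):
            yield self[i]


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels with the bead indices of each lipid.

    ``labels[k]`` is one of ``"upper"``, ``"lower"``, ``"unassigned"`` for the
    k-th lipid; ``lipid_beads[k]`` are that lipid's bead indices in the frame.
    """

    labels: np.ndarray
    lipid_beads: list[np.ndarray] = field(repr=False)

    @property
    def n_lipids(self) -> int:
        return len(self.labels)

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))

    def bead_labels(self, n_beads: int) -> np.ndarray:
        """Per-bead label array ('' for beads not belonging to a lipid)."""
        out = np.full(n_beads, "", dtype=object)
        for lab, idx in zip(self.labels, self.lipid_beads):
            out[idx] = lab
        return out


# ---------------------------------------------------------------------------
# File reading / writing (MDAnalysis backend)


def _universe_to_frame(u) -> BeadFrame:
    atoms = u.atoms
    try:
        chains = np.asarray(atoms.chainIDs, dtype=object)
    except Exception:
        chains = np.full(len(atoms), "", dtype=object)
    dims = u.dimensions
    if dims is None or np.all(dims[:3] == 0):
        raise ParseError("missing box information in coordinate file")
    return BeadFrame(
        chains=chains,
        resids=np.asarray(atoms.resids, dtype=int),
        resnames=np.asarray(atoms.resnames, dtype=object),
        names=np.asarray(atoms.names, dtype=object),
        positions=np.asarray(atoms.positions, dtype=float),
        box=np.asarray(dims[:3], dtype=float),
    )


def _locate_bad_gro_line(path: Path) -> int | None:
    """Best-effort scan for the first malformed fixed-column GRO atom line."""
    try:
        lines = Path(path).read_text().splitlines()
        n_atoms = int(lines[1].strip())
        for ln in range(2, 2 + n_atoms):
            text = lines[ln]
            if len(text) < 44:
                return ln + 1
            for lo, hi in ((20, 28), (28, 36), (36, 44)):
                float(text[lo:hi])
    except (ValueError, IndexError):
        return (ln + 1) if "ln" in locals() else None
    return None


def read_coordinates(path: str | Path, format: str | None = None) -> BeadFrame:
    """Read a single-frame GRO or PDB coordinate file into a :class:`BeadFrame`.

    GRO positions (nm) are converted to Å.  Malformed fixed-column lines raise
    :class:`ParseError` naming the offending line where it can be located.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    try:
        u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # MDAnalysis raises assorted ValueErrors/IOErrors
        if fmt == "GRO":
            bad = _locate_bad_gro_line(path)
            if bad is not None:
                raise ParseError(f"{path}: malformed GRO line {bad}") from exc
        raise ParseError(f"{path}: {exc}") from exc
    return _universe_to_frame(u)


def read_trajectory(topology: str | Path | BeadFrame, path: str | Path,
                    format: str | None = None,
                    topology_path: str | Path | None = None) -> Trajectory:
    """Read a trajectory (XTC/TRR/DCD/multi-model PDB) against a topology.

    ``topology`` may be a file path or an already-read :class:`BeadFrame`
    (in which case ``topology_path`` must point at the file MDAnalysis should
    use for atom labels).  The per-frame atom count must match the topology.
    """
    import MDAnalysis as mda

    if isinstance(topology, BeadFrame):
        if topology_path is None:
            raise ValueError("topology_path required when passing a BeadFrame")
        top_frame, top_file = topology, Path(topology_path)
    else:
        top_file = Path(topology)
        top_frame = read_coordinates(top_file)

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kwargs = {"format": format.upper()} if format else {}
    try:
        u = mda.Universe(str(top_file), str(path), **kwargs)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(u.atoms) != top_frame.n_beads:
        raise ParseError(
            f"{path}: trajectory atom count {len(u.atoms)} does not match "
            f"topology ({top_frame.n_beads} beads)")

    coords, boxes = [], []
    try:
        for ts in u.trajectory:
            coords.append(ts.positions.astype(float).copy())
            dims = ts.dimensions
            if dims is None or np.all(dims[:3] == 0):
                boxes.append(top_frame.box.copy())  # formats without per-frame cells
            else:
                boxes.append(np.asarray(dims[:3], dtype=float))
    except Exception as exc:
        raise ParseError(f"{path}: unreadable frame: {exc}") from exc
    return Trajectory(top_frame, np.array(coords), np.array(boxes))


def write_gro(frame: BeadFrame, path: str | Path) -> None:
    """Write a single frame as GRO (Å converted to nm by the writer)."""
    import MDAnalysis as mda

    u = _frame_to_universe(frame)
    with mda.Writer(str(path), n_atoms=frame.n_beads) as w:
        w.write(u.atoms)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write all frames to XTC/TRR/DCD or multi-model PDB (by extension)."""
    import MDAnalysis as mda

    u = _frame_to_universe(traj.topology, traj)
    with mda.Writer(str(path), n_atoms=traj.topology.n_beads) as w:
        for _ in u.trajectory:
            w.write(u.atoms)


def _frame_to_universe(frame: BeadFrame, traj: Trajectory | None = None):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    # residue grouping must match the frame's segmentation
    segments = frame.residue_segments()
    n_res = len(segments)
    atom_resindex = np.empty(frame.n_beads, dtype=int)
    for ri, idx in enumerate(segments):
        atom_resindex[idx] = ri
    u = mda.Universe.empty(frame.n_beads, n_residues=n_res,
                           atom_resindex=atom_resindex, trajectory=False)
    u.add_TopologyAttr("names", list(frame.names))
    u.add_TopologyAttr("resnames", [str(frame.resnames[idx[0]]) for idx in segments])
    u.add_TopologyAttr("resids", [int(frame.resids[idx[0]]) for idx in segments])
    u.add_TopologyAttr("chainIDs", [str(c) if c else "X" for c in frame.chains])
    u.add_TopologyAttr("segids", ["SYS"])
    if traj is None:
        coords = frame.positions[None, :, :].astype(np.float32)
        dims = np.array([[*frame.box, 90.0, 90.0, 90.0]], dtype=np.float32)
    else:
        coords = traj.coordinates.astype(np.float32)
        dims = np.hstack([traj.boxes, np.full((len(traj), 3), 90.0)]).astype(np.float32)
    u.load_new(coords, format=MemoryReader, dimensions=dims)
    return u


# ---------------------------------------------------------------------------
# Selections


_SELECTION_KEYWORDS = {"resname", "bead", "name", "chain", "resid"}


def select_beads(frame: BeadFrame, expression: str) -> np.ndarray:
    """Evaluate a selection expression, returning ordered bead indices.

    Grammar: predicates joined by ``and``; each predicate is a keyword
    (``resname``, ``bead``/``name``, ``chain``, ``resid``) followed by one or
    more values, OR-ed together.  ``resid`` values may be single ids or
    inclusive ranges ``lo-hi``.  Example::

        resname POPE and bead GL1
        resid 106-134 and chain S
    """
    mask = np.ones(frame.n_beads, dtype=bool)
    clauses = [c.strip() for c in expression.split(" and ")]
    if not expression.strip():
        raise SelectionError("empty selection expression")
    for clause in clauses:
        tokens = clause.split()
        if len(tokens) < 2:
            raise SelectionError(f"incomplete predicate: {clause!r}")
        keyword, values = tokens[0], tokens[1:]
        if keyword not in _SELECTION_KEYWORDS:
            raise SelectionError(f"unknown selection keyword: {keyword!r}")
        if keyword == "resname":
            mask &= np.isin(frame.resnames.astype(str), values)
        elif keyword in ("bead", "name"):
            mask &= np.isin(frame.names.astype(str), values)
        elif keyword == "chain":
            mask &= np.isin(frame.chains.astype(str), values)
        else:  # resid
            sub = np.zeros(frame.n_beads, dtype=bool)
            for v in values:
                if "-" in v[1:]:  # allow plain negatives to fail naturally
                    lo_s, hi_s = v.split("-", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid range: {v!r}") from exc
                    sub |= (frame.resids >= lo) & (frame.resids <= hi)
                else:
                    try:
                        sub |= frame.resids == int(v)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid: {v!r}") from exc
            mask &= sub
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        logger.warning("selection %r matched no beads", expression)
    return indices


# ---------------------------------------------------------------------------
# Leaflet assignment


def assign_leaflets(frame: BeadFrame,
                    head_bead_names: Sequence[str] = ("PO4",),
                    tail_bead_names: Sequence[str] = ("C1A", "C2A", "C1B", "C2B"),
                    ) -> LeafletAssignment:
    """Assign each lipid to the upper or lower leaflet by head→tail orientation.

    A residue counts as a lipid if it carries at least one of the named head
    or tail beads.  A lipid is ``upper`` when its head-bead centroid lies above
    its tail-bead centroid along +z, ``lower`` when below, and ``unassigned``
    when either bead set is missing (warned, never fatal).  Orientation-based
    assignment stays correct for strongly deformed membranes where a global
    z-median plane would misclassify.
    """
    head_set, tail_set = set(head_bead_names), set(tail_bead_names)
    labels: list[str] = []
    lipids: list[np.ndarray] = []
    z = frame.positions[:, 2]
    names = frame.names.astype(str)
    for idx in frame.residue_segments():
        seg_names = names[idx]
        heads = idx[np.isin(seg_names, list(head_set))]
        tails = idx[np.isin(seg_names, list(tail_set))]
        if len(heads) == 0 and len(tails) == 0:
            continue  # not a lipid (e.g. protein residue)
        lipids.append(idx)
        if len(heads) == 0 or len(tails) == 0:
            logger.warning("lipid %s %d lacks %s beads; unassigned",
                           frame.resnames[idx[0]], frame.resids[idx[0]],
                           "head" if len(heads) == 0 else "tail")
            labels.append("unassigned")
            continue
        dz = z[heads].mean() - z[tails].mean()
        if dz > 0:
            labels.append("upper")
        elif dz < 0:
            labels.append("lower")
        else:
            labels.append("unassigned")
    return LeafletAssignment(np.array(labels, dtype=object), lipids)
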