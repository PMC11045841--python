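"""Trajectory ensemble I/O.

A *trajectory* is a time-ordered sequence of molecular geometries (multi-frame
XYZ, coordinates in Angstrom on a nominally 1 fs grid) together with a
per-frame electronic-state label (0 = S0, 1 = S1, 2 = S2) and, optionally, a
list of surface-hop events.  An *ensemble* bundles many trajectories sharing
one atom ordering plus the dihedral map used by :mod:`rotordyn.geometry`.

Two on-disk layouts are supported:

``xyz_dir``
    One multi-frame XYZ file per trajectory (``<id>.xyz``) with ``time=`` and
    ``state=`` tokens on the comment line, plus an optional tab-separated hop
    sidecar ``hops.tsv`` (columns: traj_id, frame, from_state, to_state).

``xyz_concat``
    A single XYZ file holding all trajectories back to back; a new trajectory
    starts whenever the ``traj=`` token on the comment line changes.

When no state information exists, all frames default to S1 and hops must be
supplied through the sidecar or inferred downstream; the reader never guesses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import ParseError, StructuralError

logger = logging.getLogger(__name__)

HOP_SIDECAR_NAME = "hops.tsv"
HOP_SIDECAR_COLUMNS = ("traj_id", "frame", "from_state", "to_state")

_TOKEN_RE = re.compile(r"(\w+)=([^\s]+)")


@dataclass(frozen=True)
class HopEvent:
    """A single surface hop at ``frame_index`` (the first frame on ``to_state``)."""

    frame_index: int
    from_state: int
    to_state: int

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise ValueError("hop must change the electronic state")


@dataclass
class Trajectory:
    """One quantum-classical trajectory on the shared atom ordering.

    Attributes
    ----------
    id : str
        Unique trajectory label within its ensemble.
    atom_labels : list of str
        Element symbols in XYZ order.
    times : ndarray, shape (n_frames,)
        Frame times in fs, strictly increasing.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Angstrom.
    states : ndarray of int, shape (n_frames,)
        Per-frame electronic state (0, 1 or 2).
    hops : list of HopEvent
        Recorded hops, ordered by frame index.
    meta : dict
        Free-form annotations (e.g. ``{"system": "rh_like"}``).
    """

    id: str
    atom_labels: list[str]
    times: np.ndarray
    coords: np.ndarray
    states: np.ndarray
    hops: list[HopEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def validate(self) -> None:
        if self.coords.shape != (self.n_frames, len(self.atom_labels), 3):
            raise StructuralError(
                f"trajectory {self.id}: coords shape {self.coords.shape} "
                f"inconsistent with {self.n_frames} frames x {len(self.atom_labels)} atoms"
            )
        if len(self.states) != self.n_frames:
            raise StructuralError(f"trajectory {self.id}: state/frame length mismatch")
        if not np.all(np.isin(self.states, (0, 1, 2))):
            raise StructuralError(f"trajectory {self.id}: states outside {{0,1,2}}")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise StructuralError(f"trajectory {self.id}: times not strictly increasing")
        for hop in self.hops:
            if not 0 <= hop.frame_index < self.n_frames:
                raise StructuralError(
                    f"trajectory {self.id}: hop frame {hop.frame_index} out of bounds"
                )


@dataclass
class Ensemble:
    """A set of trajectories sharing atom count, dt and dihedral map."""

    trajectories: list[Trajectory]
    dihedral_map: dict = field(default_factory=dict)
    dt: float = 1.0

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def validate(self) -> None:
        if self.dt <= 0:
            raise StructuralError("dt must be positive")
        counts = {t.n_atoms for t in self.trajectories}
        if len(counts) > 1:
            raise StructuralError(f"inconsistent atom counts across trajectories: {counts}")
        for t in self.trajectories:
            t.validate()


def _parse_comment(comment: str) -> dict:
    return {m.group(1): m.group(2) for m in _TOKEN_RE.finditer(comment)}


def _read_xyz_frames(path: Path) -> Iterator[tuple[dict, list[str], np.ndarray]]:
    """Yield (comment tokens, atom labels, coords) per frame of a multi-frame XYZ."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, frame_no = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: frame {frame_no}: bad atom-count line {lines[i]!r}") from exc
        if i + 2 + natoms > len(lines):
            raise ParseError(
                f"{path}: frame {frame_no}: truncated frame "
                f"(atom-count header says {natoms})"
            )
        tokens = _parse_comment(lines[i + 1])
        labels, xyz = [], np.empty((natoms, 3))
        for k in range(natoms):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: frame {frame_no}: atom line {k} malformed "
                    f"(atom-count header says {natoms})"
                )
            labels.append(parts[0])
            try:
                xyz[k] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ParseError(f"{path}: frame {frame_no}: atom line {k}: {exc}") from exc
        yield tokens, labels, xyz
        i += 2 + natoms
        frame_no += 1


def _frames_to_trajectory(
    traj_id: str, frames: Sequence[tuple[dict, list[str], np.ndarray]], source: str
) -> Trajectory:
    if not frames:
        raise ParseError(f"{source}: no frames for trajectory {traj_id}")
    labels = frames[0][1]
    times, states, coords = [], [], []
    for fi, (tokens, flabels, xyz) in enumerate(frames):
        if flabels != labels:
            raise ParseError(f"{source}: frame {fi}: atom labels changed mid-trajectory")
        times.append(float(tokens.get("time", fi)))
        states.append(int(tokens.get("state", 1)))
        coords.append(xyz)
    traj = Trajectory(
        id=traj_id,
        atom_labels=labels,
        times=np.asarray(times, dtype=float),
        coords=np.asarray(coords, dtype=float),
        states=np.asarray(states, dtype=int),
    )
    traj.validate()
    return traj


def _read_hop_sidecar(path: Path) -> dict[str, list[HopEvent]]:
    hops: dict[str, list[HopEvent]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "traj_id":  # header
                continue
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno + 1}: expected 4 tab-separated fields")
            tid, frame, frm, to = parts
            hops.setdefault(tid, []).append(
                HopEvent(frame_index=int(frame), from_state=int(frm), to_state=int(to))
            )
    return hops


def read_ensemble(root: str | Path, layout: str = "xyz_dir", dihedral_map: dict | None = None) -> Ensemble:
    """Read a trajectory ensemble from ``root`` in the given layout.

    Parameters
    ----------
    root : path
        Directory (``xyz_dir``) or file (``xyz_concat``).
    layout : {"xyz_dir", "xyz_concat"}
        On-disk dialect, see module docstring.
    dihedral_map : dict, optional
        Named atom-index quadruples (and BLA bond lists) attached to the
        returned ensemble; analysis stages require it but reading does not.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    if layout == "xyz_dir":
        trajectories = [
            _frames_to_trajectory(p.stem, list(_read_xyz_frames(p)), str(p))
            for p in sorted(root.glob("*.xyz"))
        ]
        sidecar = root / HOP_SIDECAR_NAME
        if sidecar.exists():
            hop_map = _read_hop_sidecar(sidecar)
            for traj in trajectories:
                traj.hops = hop_map.get(traj.id, [])
    elif layout == "xyz_concat":
        groups: dict[str, list] = {}
        order: list[str] = []
        for fi, frame in enumerate(_read_xyz_frames(root)):
            tid = frame[0].get("traj", "0")
            if tid not in groups:
                groups[tid] = []
                order.append(tid)
            groups[tid].append(frame)
        trajectories = [
            _frames_to_trajectory(tid, groups[tid], str(root)) for tid in order
        ]
        sidecar = root.with_name(HOP_SIDECAR_NAME)
        if sidecar.exists():
            hop_map = _read_hop_sidecar(sidecar)
            for traj in trajectories:
                traj.hops = hop_map.get(traj.id, [])
    else:
        raise ValueError(f"unknown layout {layout!r}")

    dts = [
        float(np.median(np.diff(t.times))) for t in trajectories if t.n_frames > 1
    ]
    dt = float(np.median(dts)) if dts else 1.0
    ens = Ensemble(trajectories=trajectories, dihedral_map=dihedral_map or {}, dt=dt)
    ens.validate()
    return ens


def write_ensemble(ensemble: Ensemble, root: str | Path) -> list[Path]:
    """Write one multi-frame XYZ per trajectory plus a hop sidecar under ``root``.

    Float formatting is fixed at ``%.6f`` so repeated writes are bit-stable.
    Returns the list of written paths (sidecar last).
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not ensemble.trajectories:
        logger.warning("writing empty ensemble to %s", root)
    for traj in ensemble.trajectories:
        path = root / f"{traj.id}.xyz"
        with open(path, "w") as fh:
            for fi in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\n")
                fh.write(f"time={traj.times[fi]:.6f} state={traj.states[fi]}\n")
                for label, (x, y, z) in zip(traj.atom_labels, traj.coords[fi]):
                    fh.write(f"{label} {x:.6f} {y:.6f} {z:.6f}\n")
        written.append(path)
    sidecar = root / HOP_SIDECAR_NAME
    with open(sidecar, "w") as fh:
        fh.write("\t".join(HOP_SIDECAR_COLUMNS) + "\n")
        for traj in ensemble.trajectories:
            for hop in traj.hops:
                fh.write(f"{traj.id}\t{hop.frame_index}\t{hop.from_state}\t{hop.to_state}\n")
    written.append(sidecar)
    return written
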