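"""S1->S0 decay-point detection, decay observables and reactivity labels.

Each trajectory contributes one decay point: the first S1->S0 surface hop.
Observables (angles and velocities) are evaluated on the *last S1 frame*,
i.e. the frame immediately before the hop, using a backward finite
difference so the velocity is defined before the ground-state force field
takes over.  Reactivity is read from the unwrapped twist angle alpha at the
final frame: within +/-tol of -180 deg (mod 360) the trajectory reached the
isomerized product (reactive), within +/-tol of 0 deg it returned to the
reactant (unreactive), anything else is labelled undecided and excluded
from fraction denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NoDecayError
from .geometry import GeometrySeries
from .trajectory_io import HopEvent, Trajectory

logger = logging.getLogger(__name__)

#: fixed column order of the hop table consumed by ensemble_stats
HOP_TABLE_COLUMNS = (
    "traj_id",
    "hop_time",
    "alpha_decay",
    "tau_decay",
    "delta_op_decay",
    "dtau_decay",
    "dalpha_decay",
    "ddelta_op_decay",
    "drho_decay",
    "end_alpha",
    "label",
    "velocity_defined",
    "short_tail",
)


@dataclass
class HopRecord:
    """Per-trajectory decay-point summary.

    ``hop_time`` is the time of the last S1 frame (the decay point); all
    angles are degrees, velocities deg/fs (backward difference into the decay
    point).  ``label`` is ``"reactive"``, ``"unreactive"`` or ``"undecided"``;
    ``velocity_defined`` is False when the hop happened too early for a
    backward difference; ``short_tail`` flags fewer than 5 post-hop frames
    (classification unstable).
    """

    traj_id: str
    hop_time: float
    alpha_decay: float
    tau_decay: float
    delta_op_decay: float
    dtau_decay: float
    dalpha_decay: float
    ddelta_op_decay: float
    drho_decay: float
    end_alpha: float
    label: str
    velocity_defined: bool = True
    short_tail: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def reactive(self) -> bool:
        return self.label == "reactive"

    @property
    def classified(self) -> bool:
        return self.label in ("reactive", "unreactive")


def find_decay(traj: Trajectory) -> HopEvent:
    """Return the first S1->S0 transition of the trajectory.

    Prefers the per-frame state sequence; falls back to the recorded hop
    events when states carry no transition (e.g. sidecar-only ensembles).
    Raises :class:`NoDecayError` when neither source shows an S1->S0 hop.
    """
    states = traj.states
    if len(states) > 1:
        trans = np.flatnonzero((states[:-1] == 1) & (states[1:] == 0))
        if trans.size:
            idx = int(trans[0]) + 1
            return HopEvent(frame_index=idx, from_state=1, to_state=0)
    for hop in traj.hops:
        if hop.from_state == 1 and hop.to_state == 0:
            return hop
    raise NoDecayError(f"trajectory {traj.id}: no S1->S0 transition")


def _wrap180(angle: float) -> float:
    """Map an angle to (-180, 180]."""
    wrapped = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def classify(
    traj: Trajectory,
    alpha: GeometrySeries,
    hop: HopEvent,
    tol: float = 45.0,
    secondary_twist: GeometrySeries | None = None,
) -> str:
    """Label a trajectory by the ground-state configuration it reached.

    ``reactive`` iff the final-frame unwrapped alpha lies within ``tol``
    degrees of the isomerized product (+/-180 mod 360), ``unreactive`` iff
    within ``tol`` of the reactant (0 mod 360), else ``undecided``.

    ``secondary_twist`` enables the multi-bond (bicycle-pedal) hook: when the
    primary twist ends at the reactant but a second isomerizing dihedral ends
    at its product configuration, the trajectory counts as reactive.
    Disabled by default.
    """
    if hop.frame_index >= traj.n_frames:
        raise ValueError("hop beyond trajectory end; cannot classify")
    end_alpha = float(alpha.values[-1])
    wrapped = _wrap180(end_alpha)
    dist_product = 180.0 - abs(wrapped)  # distance to +/-180
    dist_reactant = abs(wrapped)
    if dist_product <= tol:
        return "reactive"
    if dist_reactant <= tol:
        if secondary_twist is not None:
            second = _wrap180(float(secondary_twist.values[-1]))
            if 180.0 - abs(second) <= tol:
                return "reactive"
        return "unreactive"
    return "undecided"


def _backward_velocity(series: GeometrySeries, idx: int, dt: float) -> float:
    if idx < 1:
        return float("nan")
    return float((series.values[idx] - series.values[idx - 1]) / dt)


def decay_observables(
    traj: Trajectory,
    series: dict[str, GeometrySeries],
    hop: HopEvent,
    tol: float = 45.0,
    secondary_twist: GeometrySeries | None = None,
) -> HopRecord:
    """Evaluate all decay-point observables and attach the reactivity label.

    The decay point is the last S1 frame (``hop.frame_index - 1``); its
    velocities use the backward difference over the actual frame spacing.
    A hop at frame 0 or 1 leaves the velocity undefined and the record is
    excluded from velocity statistics downstream.
    """
    dec = hop.frame_index - 1
    if dec < 0:
        raise ValueError("hop at frame 0 leaves no S1 frame")
    alpha = series["alpha"]
    dt = float(traj.times[dec] - traj.times[dec - 1]) if dec >= 1 else float("nan")
    vel = {
        name: _backward_velocity(series[name], dec, dt) if name in series else float("nan")
        for name in ("tau", "alpha", "delta_op", "rho")
    }
    n_post = traj.n_frames - 1 - dec
    label = classify(traj, alpha, hop, tol=tol, secondary_twist=secondary_twist)
    if n_post < 5:
        logger.warning("trajectory %s: only %d post-hop frames", traj.id, n_post)
    return HopRecord(
        traj_id=traj.id,
        hop_time=float(traj.times[dec]),
        alpha_decay=float(alpha.values[dec]),
        tau_decay=float(series["tau"].values[dec]),
        delta_op_decay=float(series["delta_op"].values[dec]),
        dtau_decay=vel["tau"],
        dalpha_decay=vel["alpha"],
        ddelta_op_decay=vel["delta_op"],
        drho_decay=vel["rho"],
        end_alpha=float(alpha.values[-1]),
        label=label,
        velocity_defined=dec >= 1,
        short_tail=n_post < 5,
    )


def analyze_ensemble(
    ensemble, tol: float = 45.0, secondary_name: str | None = None
) -> tuple[list[HopRecord], list[str]]:
    """Derive series and decay records for every trajectory of an ensemble.

    Returns the records plus the ids of trajectories excluded because they
    never decayed within the propagation horizon.
    """
    from .geometry import derive_series

    records, undecayed = [], []
    for traj in ensemble:
        series = derive_series(traj, ensemble.dihedral_map)
        try:
            hop = find_decay(traj)
        except NoDecayError:
            undecayed.append(traj.id)
            continue
        secondary = series.get(secondary_name) if secondary_name else None
        records.append(
            decay_observables(traj, series, hop, tol=tol, secondary_twist=secondary)
        )
    if undecayed:
        logger.info("%d trajectories without S1->S0 decay excluded", len(undecayed))
    return records, undecayed


def records_to_frame(records: list[HopRecord]) -> pd.DataFrame:
    rows = [
        {f.name: getattr(r, f.name) for f in fields(HopRecord) if f.name != "meta"}
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(HOP_TABLE_COLUMNS))


def write_hop_table(records: list[HopRecord], path: str | Path) -> Path:
    """Write the delimited-text hop table (one row per trajectory)."""
    path = Path(path)
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_hop_table(path: str | Path) -> list[HopRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        HopRecord(**{k: row[k] for k in HOP_TABLE_COLUMNS})
        for _, row in df.iterrows()
    ]
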