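"""Kinematic generator of labelled photoisomerization trajectory ensembles.

Each synthetic trajectory prescribes the twist angle ``alpha`` as a
monotonic drift toward the -90 degree decay region plus an oscillatory
component, and the wag coordinate ``delta_op`` as the superposition of a
fast wag (tens of fs, the hydrogen-out-of-plane-like mode) and an optional
slow promoter oscillation (hundreds of fs, a ring-inversion-like mode):

    osc(t)      = A_wag  * sin(2*pi*t/T_wag  + phi_wag)
                + A_prom * sin(2*pi*t/T_prom + phi_prom)
    alpha(t)    = alpha_0 + drift * t + c_alpha * osc(t)
    delta_op(t) = osc(t),   beta = alpha - delta_op

so tau = alpha - 0.5*delta_op carries the drift plus a
``(c_alpha - 0.5) * osc`` oscillation.  A surface hop is placed at the
first discrete-grid crossing of alpha below the (jittered) crossing angle,
accepted with a configurable probability.  The outcome encodes the
velocity-threshold reactivity rule motivated by Landau-Zener theory: with
``v`` the backward-difference tau velocity at the decay point,

    v < -theta        -> reactive   (fast counterclockwise bond breaking)
    v > +theta        -> unreactive
    |v| <= theta      -> Bernoulli(q)   (direction randomized at low speed)

After the hop alpha relaxes exponentially to -180 deg (reactive) or 0 deg
(unreactive) and the wag oscillation is damped on the same time constant.
Crossings too close to the horizon for the relaxation to settle are
rejected (trajectory emitted undecayed and ledger-marked).  Angles are
embedded as 6-atom Cartesian frames (C1, C2, C3, C4, R1, R4) so the full
geometric pipeline runs end to end; every random draw comes from one
seeded generator, making ensembles bit-identical per seed.

A ground-truth ledger records, per trajectory, the prescribed series, hop
frame, the exact finite-difference decay velocity and the label assigned by
the rule above, serving as the oracle for classifier round-trip tests.  A
ring-inversion-like series proportional to the promoter component is stored
alongside so promoter-correlation analyses can run on synthetic data.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory_io import Ensemble, HopEvent, Trajectory

ATOM_LABELS = ["C", "C", "C", "C", "H", "H"]
#: dihedral map of the 6-atom embedding (atom order C1, C2, C3, C4, R1, R4)
EMBED_DIHEDRAL_MAP = {
    "alpha": (0, 1, 2, 3),
    "beta": (4, 1, 2, 5),
    "bla_single": [(0, 1), (2, 3)],
    "bla_double": [(1, 2)],
}
_R_CC, _R_DB, _R_CH = 1.45, 1.40, 1.08
_SIN60, _COS60 = np.sin(np.radians(60.0)), np.cos(np.radians(60.0))


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic ensemble (angles deg, times fs)."""

    n_traj: int = 200
    dt: float = 1.0
    horizon: float = 260.0
    drift_mean: float = -1.5        # mean d(alpha_I)/dt, deg/fs
    drift_sd: float = 0.5
    drift_clip: tuple[float, float] = (-3.0, -0.5)
    wag_amplitude: float = 29.0     # deg; fast delta_op oscillation
    wag_period: float = 40.0
    wag_phase_sd: float = 0.4       # rad; cross-trajectory coherence
    wag_phase_mean: float = 0.0
    promoter_amplitude: float = 0.0  # deg; slow ring-inversion-like mode
    promoter_period: float = 250.0
    promoter_phase_sd: float = 0.8
    promoter_phase_mean: float = 0.0
    alpha0_mean: float = -10.0      # CCW pre-twist of the reactant
    alpha0_sd: float = 3.0
    alpha_osc_fraction: float = 0.2  # share of osc placed in alpha (rest in beta)
    cross_angle: float = -90.0
    cross_jitter_sd: float = 3.0
    hop_prob: float = 1.0
    threshold: float = 1.0          # deg/fs; reactivity speed threshold
    q_subthreshold: float = 0.5     # reactive probability below threshold
    relax_tau: float = 30.0         # fs; post-hop exponential relaxation
    rho_scale: float = 2.0          # ring-inversion series per unit promoter
    seed: int = 0
    system: str = "custom"


PRESETS: dict[str, GeneratorConfig] = {
    # fast, coherent rotor: strong 40 fs wag promoter, early decay onset
    "rh_like": GeneratorConfig(
        horizon=290.0,
        drift_mean=-1.35,
        drift_clip=(-3.0, -0.45),
        system="rh_like",
    ),
    # slow solvated rotor: weak incoherent wag plus a 250 fs promoter
    "naip_like": GeneratorConfig(
        horizon=720.0,
        drift_mean=-0.4,
        drift_sd=0.2,
        drift_clip=(-0.65, -0.2),
        wag_amplitude=8.0,
        wag_period=45.0,
        wag_phase_sd=1.5,
        promoter_amplitude=25.0,
        promoter_period=250.0,
        promoter_phase_sd=0.8,
        alpha0_sd=2.0,
        cross_jitter_sd=3.0,
        relax_tau=40.0,
        # effective sub-threshold reactive probability; below 1/2 because a
        # slow rotor that reaches the crossing with the wrong velocity phase
        # re-forms the reactant slightly more often than the product
        q_subthreshold=0.42,
        system="naip_like",
    ),
    # isolated rotor: same promoter with reduced phase jitter (coherent ring
    # inversion) and slightly faster drift
    "naip_gas_like": GeneratorConfig(
        horizon=720.0,
        drift_mean=-0.45,
        drift_sd=0.2,
        drift_clip=(-0.7, -0.2),
        wag_amplitude=8.0,
        wag_period=45.0,
        wag_phase_sd=0.5,
        promoter_amplitude=30.0,
        promoter_period=250.0,
        promoter_phase_sd=0.15,
        alpha0_sd=2.0,
        relax_tau=40.0,
        system="naip_gas_like",
    ),
}


def get_preset(name: str, **overrides) -> GeneratorConfig:
    cfg = copy.deepcopy(PRESETS[name])
    return dataclasses.replace(cfg, **overrides)


@dataclass
class LedgerEntry:
    traj_id: str
    drift: float
    alpha0: float
    wag_phase: float
    promoter_phase: float
    hop_frame: int | None           # first S0 frame, None if undecayed
    decay_time: float
    dtau_decay: float               # backward difference at the decay point
    dtau_decay_analytic: float      # d(tau)/dt of the prescribed curve
    label: str                      # reactive | unreactive | undecayed
    boundary: bool                  # |dtau_decay| within eps of the threshold
    alpha: np.ndarray = field(repr=False, default=None)
    beta: np.ndarray = field(repr=False, default=None)
    rho: np.ndarray = field(repr=False, default=None)


@dataclass
class GroundTruthLedger:
    config: GeneratorConfig
    entries: list[LedgerEntry]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [
            {
                k: getattr(e, k)
                for k in (
                    "traj_id", "drift", "alpha0", "wag_phase", "promoter_phase",
                    "hop_frame", "decay_time", "dtau_decay",
                    "dtau_decay_analytic", "label", "boundary",
                )
            }
            for e in self.entries
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g")
        return path


def embed_xyz(alpha, beta) -> np.ndarray:
    """Cartesian 6-atom frame(s) carrying the two mapped dihedrals.

    Atoms are C1, C2, C3, C4, R1, R4 with C2 at the origin and the C2=C3
    bond along z; sp2-like 120-degree bond angles.  The C1-C2-C3-C4 dihedral
    reads back ``alpha`` and R1-C2-C3-R4 reads back ``beta`` (both in
    degrees).  Accepts scalars -> (6, 3) or equal-length arrays -> (n, 6, 3).
    """
    alpha = np.radians(np.asarray(alpha, dtype=float))
    beta = np.radians(np.asarray(beta, dtype=float))
    scalar = alpha.ndim == 0
    alpha, beta = np.atleast_1d(alpha), np.atleast_1d(beta)
    n = len(alpha)
    frames = np.empty((n, 6, 3))
    frames[:, 1] = 0.0                                    # C2
    frames[:, 2] = (0.0, 0.0, _R_DB)                      # C3
    frames[:, 0] = (_R_CC * _SIN60, 0.0, -_R_CC * _COS60)  # C1, azimuth 0
    frames[:, 4] = (-_R_CH * _SIN60, 0.0, -_R_CH * _COS60)  # R1, azimuth pi
    frames[:, 3, 0] = _R_CC * _SIN60 * np.cos(alpha)      # C4, azimuth alpha
    frames[:, 3, 1] = _R_CC * _SIN60 * np.sin(alpha)
    frames[:, 3, 2] = _R_DB + _R_CC * _COS60
    frames[:, 5, 0] = _R_CH * _SIN60 * np.cos(beta + np.pi)  # R4, azimuth beta+pi
    frames[:, 5, 1] = _R_CH * _SIN60 * np.sin(beta + np.pi)
    frames[:, 5, 2] = _R_DB + _R_CH * _COS60
    return frames[0] if scalar else frames


def _first_accepted_crossing(alpha, cross, rng, hop_prob, last_allowed) -> int | None:
    """First frame strictly below ``cross`` whose predecessor is not, accepted
    with probability ``hop_prob``; crossings after ``last_allowed`` rejected."""
    below = alpha < cross
    crossings = np.flatnonzero(~below[:-1] & below[1:]) + 1
    for h in crossings:
        if h < 2:
            continue
        if h > last_allowed:
            return None
        if hop_prob >= 1.0 or rng.random() < hop_prob:
            return int(h)
    return None


def generate(config: GeneratorConfig) -> tuple[Ensemble, GroundTruthLedger]:
    """Generate a labelled ensemble plus its ground-truth ledger."""
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.horizon / config.dt)) + 1
    t = np.arange(n_frames) * config.dt
    # leave room for the post-hop relaxation to settle into a basin
    last_allowed = n_frames - 1 - int(round(3 * config.relax_tau / config.dt))
    eps_boundary = 0.02  # deg/fs margin defining the threshold boundary zone

    trajectories, entries = [], []
    for i in range(config.n_traj):
        drift = float(np.clip(
            rng.normal(config.drift_mean, config.drift_sd), *config.drift_clip
        ))
        alpha0 = rng.normal(config.alpha0_mean, config.alpha0_sd)
        phi_w = rng.normal(config.wag_phase_mean, config.wag_phase_sd)
        phi_p = rng.normal(config.promoter_phase_mean, config.promoter_phase_sd)
        cross = config.cross_angle + rng.normal(0.0, config.cross_jitter_sd)

        w_wag = 2 * np.pi / config.wag_period
        w_prom = 2 * np.pi / config.promoter_period
        osc = config.wag_amplitude * np.sin(w_wag * t + phi_w)
        dosc = config.wag_amplitude * w_wag * np.cos(w_wag * t + phi_w)
        if config.promoter_amplitude:
            osc = osc + config.promoter_amplitude * np.sin(w_prom * t + phi_p)
            dosc = dosc + config.promoter_amplitude * w_prom * np.cos(w_prom * t + phi_p)
        alpha = alpha0 + drift * t + config.alpha_osc_fraction * osc
        delta_op = osc.copy()
        tau = alpha - 0.5 * delta_op
        rho = config.rho_scale * config.promoter_amplitude * np.sin(w_prom * t + phi_p)

        h = _first_accepted_crossing(alpha, cross, rng, config.hop_prob, last_allowed)
        states = np.ones(n_frames, dtype=int)
        hops: list[HopEvent] = []
        if h is None:
            label, dtau_fd, dtau_an, decay_time = "undecayed", np.nan, np.nan, np.nan
        else:
            dec = h - 1
            dtau_fd = float((tau[dec] - tau[dec - 1]) / config.dt)
            dtau_an = float(
                drift + (config.alpha_osc_fraction - 0.5) * dosc[dec]
            )
            decay_time = float(t[dec])
            if dtau_fd < -config.threshold:
                label = "reactive"
            elif dtau_fd > config.threshold:
                label = "unreactive"
            else:
                label = "reactive" if rng.random() < config.q_subthreshold else "unreactive"
            target = -180.0 if label == "reactive" else 0.0
            decay_env = np.exp(-(t[h:] - t[h]) / config.relax_tau)
            alpha[h:] = target + (alpha[h] - target) * decay_env
            delta_op[h:] = delta_op[h:] * decay_env
            states[h:] = 0
            hops.append(HopEvent(frame_index=h, from_state=1, to_state=0))
        beta = alpha - delta_op

        traj = Trajectory(
            id=f"traj_{i:04d}",
            atom_labels=list(ATOM_LABELS),
            times=t.copy(),
            coords=embed_xyz(alpha, beta),
            states=states,
            hops=hops,
            meta={"system": config.system},
        )
        trajectories.append(traj)
        entries.append(
            LedgerEntry(
                traj_id=traj.id,
                drift=drift,
                alpha0=float(alpha0),
                wag_phase=float(phi_w),
                promoter_phase=float(phi_p),
                hop_frame=h,
                decay_time=decay_time,
                dtau_decay=dtau_fd,
                dtau_decay_analytic=dtau_an,
                label=label,
                boundary=bool(
                    np.isfinite(dtau_fd)
                    and abs(abs(dtau_fd) - config.threshold) <= eps_boundary
                ),
                alpha=alpha,
                beta=beta,
                rho=rho,
            )
        )
    ensemble = Ensemble(
        trajectories=trajectories,
        dihedral_map={k: v for k, v in EMBED_DIHEDRAL_MAP.items()},
        dt=config.dt,
    )
    return ensemble, GroundTruthLedger(config=config, entries=entries)
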