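"""Minimal two-state fewest-switches surface hopping on model surfaces.

A deliberately small quantum-classical engine used as a physics-based
alternative to the kinematic generator: two nuclear modes (a periodic twist
``theta`` and a harmonic coupling/wag mode ``q``), two diabatic electronic
states coupled linearly through ``q``, classical velocity-Verlet nuclear
motion on the current adiabatic surface, and Tully's fewest-switches hopping
with an energy-based decoherence correction.  No claim of chemical accuracy
is made; the default torsional model is built so that the upper surface is
barrierless toward ``theta = -90`` degrees where the adiabatic gap closes,
echoing the conical-intersection topography of the real rotors.

Internals are in atomic units (hartree, bohr, electron mass, hbar = 1);
the public interface speaks fs and degrees.

Electronic amplitudes are propagated in the adiabatic basis with the exact
2x2 unitary propagator per substep, so the norm is conserved to machine
precision before decoherence damping.  The nonadiabatic coupling term is
evaluated from the finite-difference change of the diabatic-to-adiabatic
mixing angle between nuclear steps (the two-state equivalent of a
wavefunction-overlap scheme).  Hops rescale the velocity along the
nonadiabatic coupling vector; energetically frustrated hops reverse the
velocity component along that direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrationError
from .synthetic_data import ATOM_LABELS, EMBED_DIHEDRAL_MAP, embed_xyz
from .trajectory_io import Ensemble, HopEvent, Trajectory

FS_TO_AU = 41.341374575751
KT_300K = 9.5004e-4  # hartree


@dataclass
class DiabaticModel:
    """Two-state diabatic Hamiltonian over nuclear coordinates x.

    Subclasses provide ``potential(x) -> (2,2)`` and
    ``gradient(x) -> (ndim,2,2)`` plus a ``masses`` array (a.u.).
    """

    masses: np.ndarray

    @property
    def ndim(self) -> int:
        return len(self.masses)

    def potential(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class TorsionalModel(DiabaticModel):
    """Periodic twist + linearly coupled harmonic wag.

    Diabatic surfaces (x = (theta, q), theta in radians, q in bohr)::

        V11 = 0.5 * w0 * (1 - cos 2 theta) + 0.5 * m_q * omega^2 * q^2
        V22 = e0  - 0.5 * w1 * (1 - cos 2 theta) + 0.5 * m_q * omega^2 * q^2
        V12 = lam * q

    With ``e0 = w0 + w1`` the diabatic crossing sits exactly at
    theta = +/-90 degrees; the upper adiabat is barrierless downhill from
    the (pre-twisted) Franck-Condon region toward the crossing.
    """

    w0: float = 0.06
    w1: float = 0.04
    omega: float = 2 * np.pi / (40.0 * FS_TO_AU)  # 40 fs wag period
    lam: float = 0.005
    masses: np.ndarray = field(
        default_factory=lambda: np.array([2.5e5, 2000.0])
    )

    @property
    def e0(self) -> float:
        return self.w0 + self.w1

    def potential(self, x):
        theta, q = x
        harm = 0.5 * self.masses[1] * self.omega**2 * q**2
        v11 = 0.5 * self.w0 * (1 - np.cos(2 * theta)) + harm
        v22 = self.e0 - 0.5 * self.w1 * (1 - np.cos(2 * theta)) + harm
        v12 = self.lam * q
        return np.array([[v11, v12], [v12, v22]])

    def gradient(self, x):
        theta, q = x
        g = np.zeros((2, 2, 2))
        g[0, 0, 0] = self.w0 * np.sin(2 * theta)
        g[0, 1, 1] = -self.w1 * np.sin(2 * theta)
        dq_harm = self.masses[1] * self.omega**2 * q
        g[1, 0, 0] = dq_harm
        g[1, 1, 1] = dq_harm
        g[1, 0, 1] = g[1, 1, 0] = self.lam
        return g


@dataclass
class LinearCrossingModel(DiabaticModel):
    """1-D linear avoided crossing (V11 = f*x, V22 = -f*x, V12 = delta).

    The textbook geometry for which the Landau-Zener formula
    ``P = exp(-2 pi delta^2 / (v * |2 f|))`` gives the single-passage
    probability of switching adiabatic surfaces.
    """

    f: float = 0.005
    delta: float = 0.001
    masses: np.ndarray = field(default_factory=lambda: np.array([2000.0]))

    def potential(self, x):
        v = self.f * x[0]
        return np.array([[v, self.delta], [self.delta, -v]])

    def gradient(self, x):
        g = np.zeros((1, 2, 2))
        g[0, 0, 0] = self.f
        g[0, 1, 1] = -self.f
        return g


def _adiabatic(v: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigenvalues (ascending) and mixing angle chi of a symmetric 2x2."""
    m = 0.5 * (v[0, 0] + v[1, 1])
    d = 0.5 * (v[1, 1] - v[0, 0])
    r = np.hypot(d, v[0, 1])
    chi = 0.5 * np.arctan2(2 * v[0, 1], v[0, 0] - v[1, 1])
    return np.array([m - r, m + r]), chi


def _adiabatic_force(v, g, state) -> np.ndarray:
    """-grad of the selected adiabatic eigenvalue."""
    d = 0.5 * (v[1, 1] - v[0, 0])
    r = max(np.hypot(d, v[0, 1]), 1e-30)
    dm = 0.5 * (g[:, 0, 0] + g[:, 1, 1])
    dd = 0.5 * (g[:, 1, 1] - g[:, 0, 0])
    dr = (d * dd + v[0, 1] * g[:, 0, 1]) / r
    sign = -1.0 if state == 0 else 1.0
    return -(dm + sign * dr)


def _coupling_vector(v, g) -> np.ndarray:
    """Nonadiabatic coupling vector d12 = grad(chi) for the 2-state model."""
    a = 2 * v[0, 1]
    b = v[0, 0] - v[1, 1]
    da = 2 * g[:, 0, 1]
    db = g[:, 0, 0] - g[:, 1, 1]
    denom = max(a * a + b * b, 1e-30)
    return 0.5 * (b * da - a * db) / denom


def _wrap_half_pi(x: float) -> float:
    """Mixing-angle increments live on a mod-pi branch."""
    return (x + np.pi / 2) % np.pi - np.pi / 2


def _unitary_step(c, e0, e1, sigma, dt):
    """Exact propagator of i dc/dt = H c, H = diag(e) - i*sigma*[[0,1],[-1,0]]."""
    # H = a*I + by*sigma_y + bz*sigma_z with H01 = -i*sigma  =>  by = +sigma
    a = 0.5 * (e0 + e1)
    bz = 0.5 * (e0 - e1)
    by = sigma
    bn = np.hypot(bz, by)
    if bn < 1e-30:
        return np.exp(-1j * a * dt) * c
    cphi, sphi = np.cos(bn * dt), np.sin(bn * dt)
    # U = e^{-i a dt} (cos(|b|dt) I - i sin(|b|dt) (b.sigma)/|b|)
    u00 = cphi - 1j * sphi * bz / bn
    u11 = cphi + 1j * sphi * bz / bn
    u01 = -sphi * by / bn
    u10 = sphi * by / bn
    phase = np.exp(-1j * a * dt)
    return phase * np.array([u00 * c[0] + u01 * c[1], u10 * c[0] + u11 * c[1]])


@dataclass
class SHState:
    """Instantaneous surface-hopping state (positions a.u., time a.u.)."""

    x: np.ndarray
    v: np.ndarray
    c: np.ndarray          # complex adiabatic amplitudes (c0, c1)
    surface: int           # current adiabatic surface (0 lower, 1 upper)
    time: float = 0.0


@dataclass
class SHOptions:
    dt_nuc_fs: float = 0.25
    n_substeps: int = 20
    decoherence_c: float = 0.1       # hartree; energy-based decoherence constant
    apply_decoherence: bool = True
    energy_tol: float = 1e-4         # hartree; drift tolerance between hops
    check_energy: bool = True


@dataclass
class SHResult:
    times_fs: np.ndarray
    x: np.ndarray                 # (n_steps+1, ndim)
    surfaces: np.ndarray
    energies: np.ndarray          # total energy per step
    hops: list[tuple[int, int, int]]   # (step, from_surface, to_surface)
    frustrated: int
    max_norm_error: float


def propagate(
    model: DiabaticModel,
    init: SHState,
    horizon_fs: float,
    rng: np.random.Generator,
    options: SHOptions | None = None,
) -> SHResult:
    """Run one FSSH trajectory on the model Hamiltonian.

    Velocity-Verlet nuclear steps on the current adiabatic surface; the
    electronic amplitudes advance in ``n_substeps`` exact-unitary substeps
    with energies linearly interpolated across the nuclear step and the
    coupling term held at its finite-difference value.  After each step the
    fewest-switches probability ``g = max(0, 2 sigma Re(c_k* c_j) dt /
    |c_k|^2)`` decides hop attempts; energy-based decoherence damps the
    inactive amplitude with lifetime ``(1/|dE|) * (1 + C / E_kin)``.
    """
    opt = options or SHOptions()
    dt = opt.dt_nuc_fs * FS_TO_AU
    n_steps = int(round(horizon_fs / opt.dt_nuc_fs))
    m = model.masses

    x = init.x.astype(float).copy()
    v = init.v.astype(float).copy()
    c = init.c.astype(complex).copy()
    surf = init.surface

    pot = model.potential(x)
    grad = model.gradient(x)
    e_ad, chi = _adiabatic(pot)
    force = _adiabatic_force(pot, grad, surf)

    xs = np.empty((n_steps + 1, model.ndim))
    surfaces = np.empty(n_steps + 1, dtype=int)
    energies = np.empty(n_steps + 1)
    xs[0], surfaces[0] = x, surf
    energies[0] = 0.5 * np.sum(m * v**2) + e_ad[surf]
    hops: list[tuple[int, int, int]] = []
    frustrated = 0
    max_norm_err = 0.0
    e_ref = energies[0]

    for step in range(1, n_steps + 1):
        # --- velocity Verlet ---
        v_half = v + 0.5 * dt * force / m
        x = x + dt * v_half
        pot = model.potential(x)
        grad = model.gradient(x)
        e_new, chi_new = _adiabatic(pot)
        force = _adiabatic_force(pot, grad, surf)
        v = v_half + 0.5 * dt * force / m

        # --- electronic propagation (interpolated energies, fd coupling) ---
        sigma = _wrap_half_pi(chi_new - chi) / dt
        dts = dt / opt.n_substeps
        for k in range(opt.n_substeps):
            frac = (k + 0.5) / opt.n_substeps
            e0 = e_ad[0] + frac * (e_new[0] - e_ad[0])
            e1 = e_ad[1] + frac * (e_new[1] - e_ad[1])
            c = _unitary_step(c, e0, e1, sigma, dts)
        norm = float(np.sum(np.abs(c) ** 2))
        max_norm_err = max(max_norm_err, abs(norm - 1.0))

        # --- fewest-switches hop test ---
        other = 1 - surf
        sigma_kj = sigma if (surf, other) == (0, 1) else -sigma
        pop = max(np.abs(c[surf]) ** 2, 1e-12)
        g = 2.0 * sigma_kj * float(np.real(np.conj(c[surf]) * c[other])) * dt / pop
        if g > 0 and rng.random() < g:
            u = _coupling_vector(pot, grad)
            a_coef = 0.5 * np.sum(u**2 / m)
            b_coef = float(np.sum(u * v))
            de = e_new[other] - e_new[surf]
            disc = b_coef**2 - 4 * a_coef * de
            if disc >= 0 and a_coef > 0:
                gamma = (b_coef - np.sign(b_coef) * np.sqrt(disc)) / (2 * a_coef)
                v = v - gamma * u / m
                hops.append((step, surf, other))
                surf = other
                force = _adiabatic_force(pot, grad, surf)
                e_ref = 0.5 * np.sum(m * v**2) + e_new[surf]
            else:
                v = v - (b_coef / a_coef) * u / m if a_coef > 0 else v
                frustrated += 1

        # --- energy-based decoherence ---
        if opt.apply_decoherence:
            ekin = 0.5 * float(np.sum(m * v**2))
            de = abs(e_new[1 - surf] - e_new[surf])
            if de > 1e-12:
                tau = (1.0 / de) * (1.0 + opt.decoherence_c / max(ekin, 1e-8))
                inactive = 1 - surf
                c[inactive] *= np.exp(-dt / tau)
                n_in = np.abs(c[inactive]) ** 2
                if np.abs(c[surf]) > 1e-30:
                    c[surf] *= np.sqrt(max(1.0 - n_in, 0.0)) / np.abs(c[surf])

        e_ad, chi = e_new, chi_new
        xs[step], surfaces[step] = x, surf
        energies[step] = 0.5 * np.sum(m * v**2) + e_new[surf]
        if opt.check_energy and abs(energies[step] - e_ref) > opt.energy_tol:
            raise IntegrationError(
                f"energy drift {energies[step] - e_ref:.3e} hartree at step {step} "
                f"(tolerance {opt.energy_tol:.1e})"
            )

    times = np.arange(n_steps + 1) * opt.dt_nuc_fs
    return SHResult(
        times_fs=times,
        x=xs,
        surfaces=surfaces,
        energies=energies,
        hops=hops,
        frustrated=frustrated,
        max_norm_error=max_norm_err,
    )


@dataclass
class SamplingConfig:
    """Thermal initial conditions on the lower surface, promoted vertically."""

    temperature_kt: float = KT_300K     # hartree
    pre_twist_deg: float = -10.0        # CCW bias of the reactant well
    theta_sd_rad: float | None = None   # default: harmonic estimate from w0
    delta_scale_deg: float = 60.0       # degrees of wag per bohr of q
    stride: int = 4                     # frame decimation when exporting


def _result_to_trajectory(
    res: SHResult, traj_id: str, delta_scale_deg: float, stride: int
) -> Trajectory:
    sel = slice(None, None, stride)
    theta_deg = np.degrees(res.x[sel, 0])
    delta_op = res.x[sel, 1] * delta_scale_deg
    beta = theta_deg - delta_op
    states = res.surfaces[sel].astype(int)
    hops = []
    prev = None
    for fi, s in enumerate(states):
        if prev is not None and s != prev:
            hops.append(HopEvent(frame_index=fi, from_state=int(prev), to_state=int(s)))
        prev = s
    return Trajectory(
        id=traj_id,
        atom_labels=list(ATOM_LABELS),
        times=res.times_fs[sel].copy(),
        coords=embed_xyz(theta_deg, beta),
        states=states,
        hops=hops,
        meta={"system": "fssh"},
    )


def run_ensemble(
    model: TorsionalModel,
    n: int,
    horizon_fs: float = 200.0,
    seed: int = 0,
    sampling: SamplingConfig | None = None,
    options: SHOptions | None = None,
) -> Ensemble:
    """Sample n thermal initial conditions, promote to the upper surface, run.

    Positions/momenta are drawn from independent Gaussians matching the
    harmonic estimate of the lower-surface reactant well at ``temperature_kt``
    around the pre-twisted minimum, then placed on the upper adiabatic
    surface with unchanged geometry (a vertical excitation).  Returns an
    ensemble on the shared 6-atom embedding, directly consumable by the
    analysis pipeline.
    """
    smp = sampling or SamplingConfig()
    opt = options or SHOptions()
    rng = np.random.default_rng(seed)
    kt = smp.temperature_kt
    theta_sd = (
        smp.theta_sd_rad
        if smp.theta_sd_rad is not None
        else np.sqrt(kt / (2 * model.w0))
    )
    q_sd = np.sqrt(kt / (model.masses[1] * model.omega**2))
    trajectories = []
    for i in range(n):
        x0 = np.array(
            [
                np.radians(smp.pre_twist_deg) + rng.normal(0, theta_sd),
                rng.normal(0, q_sd),
            ]
        )
        v0 = np.array(
            [
                rng.normal(0, np.sqrt(kt / model.masses[0])),
                rng.normal(0, np.sqrt(kt / model.masses[1])),
            ]
        )
        init = SHState(x=x0, v=v0, c=np.array([0.0 + 0j, 1.0 + 0j]), surface=1)
        res = propagate(model, init, horizon_fs, rng, opt)
        trajectories.append(
            _result_to_trajectory(res, f"fssh_{i:04d}", smp.delta_scale_deg, smp.stride)
        )
    return Ensemble(
        trajectories=trajectories,
        dihedral_map={k: v for k, v in EMBED_DIHEDRAL_MAP.items()},
        dt=opt.dt_nuc_fs * smp.stride,
    )


def landau_zener_probability(model: LinearCrossingModel, v: float) -> float:
    """Closed-form single-passage surface-switch probability."""
    return float(np.exp(-2 * np.pi * model.delta**2 / (v * abs(2 * model.f))))
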