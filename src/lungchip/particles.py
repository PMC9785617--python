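"""Lagrangian particle tracing in the frozen flow field.

Each particle obeys the momentum balance

    mp dup/dt = Fd + Fb + mp (1 - rho_i/rho_p) g

with Stokes drag Fd = 3 pi mu dp (u_f - up), a Gaussian Brownian force of
per-step amplitude sqrt(6 pi kB mu T dp / dt), and the buoyant weight directed
-y (gravity perpendicular to the flow).  Fluid properties are those of the
particle's current phase (air above and inside the membrane pores, medium
below).  Two integrators are provided:

* ``inertial`` -- the linear-drag ODE is advanced with its exact exponential
  solution over each step, treating Brownian and gravitational forcing as
  piecewise-constant impulses; unconditionally stable even for tau << dt.
* ``overdamped`` -- for sub-micron particles (tau <= 1e-7 s) inertia is
  irrelevant, and the position Langevin update
  x += (u_f + v_settle) dt + sqrt(2 D dt) zeta, with D = kB T / (3 pi mu dp),
  reproduces exactly the per-step displacement statistics of the inertial
  scheme in the tau -> 0 limit.

Boundary handling per the device: the membrane top is a sticky (absorbing)
substrate; pore mouths pass particles through into the media channel (one-way
-- the underside reflects, so a transferred particle cannot return); channel
outlets remove particles; every other wall reflects specularly.

Randomness: every particle owns a counter-based Philox substream keyed by
(master seed, particle id) and consumes it only on its own updates, so results
are bit-reproducible and independent of scheduling order or ensemble makeup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .flow import FlowField, _sample_nodes
from .geometry import Domain
from .properties import KB, FluidProperties, ParticleProperties, SimulationConfig

__all__ = [
    "ACTIVE_AIR", "ACTIVE_MEDIA", "DEPOSITED", "EXITED_AIR", "EXITED_MEDIA",
    "STATUS_NAMES", "ParticleState", "ParticleEnsemble", "SimulationResult",
    "stokes_drag", "brownian_force", "buoyant_weight", "settling_velocity",
    "exponential_drag_update", "step", "apply_boundaries", "run_tracing",
]

ACTIVE_AIR = 0
ACTIVE_MEDIA = 1
DEPOSITED = 2
EXITED_AIR = 3
EXITED_MEDIA = 4
STATUS_NAMES = {
    ACTIVE_AIR: "active_air",
    ACTIVE_MEDIA: "active_media",
    DEPOSITED: "deposited",
    EXITED_AIR: "exited_air",
    EXITED_MEDIA: "exited_media",
}

_RNG_BLOCK = 2048


def stokes_drag(mu: float, dp: float, u_rel) -> np.ndarray:
    """Stokes drag F = 3 pi mu dp u_rel on a sphere, parallel to the slip velocity."""
    return 3.0 * math.pi * mu * dp * np.asarray(u_rel, dtype=float)


def brownian_force(mu: float, T: float, dp: float, dt: float, zeta, kB: float = KB) -> np.ndarray:
    """Gaussian Brownian force zeta * sqrt(6 pi kB mu T dp / dt).

    ``zeta`` components are i.i.d. standard normal draws; each force component
    then has zero mean and variance 6 pi kB mu T dp / dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return np.asarray(zeta, dtype=float) * math.sqrt(6.0 * math.pi * kB * mu * T * dp / dt)


def buoyant_weight(particle: ParticleProperties, rho_fluid: float, g: float) -> np.ndarray:
    """Net gravity force mp (1 - rho_i/rho_p) g, directed -y."""
    return np.array([0.0, -particle.mp * (1.0 - rho_fluid / particle.rho_p) * g])


def settling_velocity(particle: ParticleProperties, fluid: FluidProperties, g: float) -> float:
    """Terminal Stokes settling speed (rho_p - rho_i) g dp^2 / (18 mu), positive downward."""
    return (particle.rho_p - fluid.rho) * g * particle.dp**2 / (18.0 * fluid.mu)


def exponential_drag_update(up, u_target, tau: float, dt: float):
    """Exact one-step solution of dup/dt = (u_target - up)/tau.

    Returns ``(up_new, displacement)`` with
    up_new = u_target + (up - u_target) e^{-dt/tau} and the analytically
    integrated displacement u_target dt + (up - u_target) tau (1 - e^{-dt/tau}).
    """
    up = np.asarray(up, dtype=float)
    u_target = np.asarray(u_target, dtype=float)
    e = math.exp(-dt / tau) if np.isscalar(tau) else np.exp(-dt / np.asarray(tau))
    up_new = u_target + (up - u_target) * e
    disp = u_target * dt + (up - u_target) * (tau * (1.0 - e))
    return up_new, disp


class ParticleState(NamedTuple):
    """Read-only snapshot of one traced particle."""

    x: float
    y: float
    up_x: float
    up_y: float
    status: str
    t: float
    t_transfer: float | None
    t_exit: float | None


@dataclass
class ParticleEnsemble:
    """Structure-of-arrays state of the traced ensemble."""

    x: np.ndarray
    y: np.ndarray
    up: np.ndarray               # (n, 2) particle velocity (inertial mode)
    status: np.ndarray           # int8 codes
    t: np.ndarray                # per-particle elapsed time, s
    t_transfer: np.ndarray       # nan until pore crossing
    t_exit: np.ndarray           # nan until media-outlet crossing
    t_exit_air: np.ndarray
    y_exit: np.ndarray
    deposit_x: np.ndarray

    @classmethod
    def empty(cls, n: int) -> "ParticleEnsemble":
        nanv = np.full(n, np.nan)
        return cls(
            x=np.zeros(n), y=np.zeros(n), up=np.zeros((n, 2)),
            status=np.full(n, ACTIVE_AIR, dtype=np.int8), t=np.zeros(n),
            t_transfer=nanv.copy(), t_exit=nanv.copy(), t_exit_air=nanv.copy(),
            y_exit=nanv.copy(), deposit_x=nanv.copy(),
        )

    def __len__(self) -> int:
        return len(self.x)

    @property
    def active(self) -> np.ndarray:
        return self.status <= ACTIVE_MEDIA

    def extract(self, i: int) -> ParticleState:
        tt = self.t_transfer[i]
        te = self.t_exit[i]
        return ParticleState(
            x=float(self.x[i]), y=float(self.y[i]),
            up_x=float(self.up[i, 0]), up_y=float(self.up[i, 1]),
            status=STATUS_NAMES[int(self.status[i])], t=float(self.t[i]),
            t_transfer=None if np.isnan(tt) else float(tt),
            t_exit=None if np.isnan(te) else float(te),
        )


@dataclass
class SimulationResult:
    """Fate ledger of one tracing run.

    ``deposits`` holds the streamwise positions of particles stuck to the
    membrane-top substrate; ``transfers`` the pore-crossing times of particles
    that reached the media channel; ``media_exit_times``/``media_exit_ys`` the
    outlet-crossing records.  Fates partition the released ensemble:
    deposits + transfers-still-in-media + media exits + air exits
    (+ incomplete) = n_released.
    """

    n_released: int
    deposits: np.ndarray
    transfers: np.ndarray
    media_exit_times: np.ndarray
    media_exit_ys: np.ndarray
    n_exited_air: int
    n_incomplete_air: int = 0
    n_incomplete_media: int = 0
    complete: bool = True
    dt: float = float("nan")
    media_stride: int = 1
    ensemble: ParticleEnsemble | None = field(default=None, repr=False)

    @property
    def n_deposited(self) -> int:
        return len(self.deposits)

    @property
    def n_transferred(self) -> int:
        return len(self.transfers)

    def counts(self) -> dict:
        return {
            "released": self.n_released,
            "deposited": self.n_deposited,
            "transferred": self.n_transferred,
            "exited_air": self.n_exited_air,
            "exited_media": len(self.media_exit_times),
            "incomplete_air": self.n_incomplete_air,
            "incomplete_media": self.n_incomplete_media,
        }


@dataclass(frozen=True)
class _PhaseParams:
    mu: float
    rho: float
    D: float
    vs: float       # settling speed, positive downward (0 when gravity off)
    tau: float
    fb_vel: float   # Brownian velocity amplitude per unit sqrt(1/dt): sqrt(2D)


def _phase_params(particle, fluid, config) -> _PhaseParams:
    D = particle.diffusivity(fluid) if config.brownian else 0.0
    vs = settling_velocity(particle, fluid, config.g) if config.gravity else 0.0
    return _PhaseParams(
        mu=fluid.mu, rho=fluid.rho, D=D, vs=vs,
        tau=particle.relaxation_time(fluid), fb_vel=math.sqrt(2.0 * D),
    )


def step(
    ens: ParticleEnsemble,
    fieldf: FlowField,
    particle: ParticleProperties,
    config: SimulationConfig,
    dt,
    rng: np.random.Generator | None = None,
    z: np.ndarray | None = None,
    idx: np.ndarray | None = None,
):
    """Propose unconstrained end-of-step positions for the selected particles.

    Returns ``(idx, x1, y1)``; particle velocities (inertial mode) are updated
    in place.  ``dt`` may be a scalar or a per-particle array matching ``idx``.
    Boundary interactions are resolved afterwards by :func:`apply_boundaries`.
    """
    if idx is None:
        idx = np.flatnonzero(ens.active)
    n = len(idx)
    if z is None:
        z = rng.standard_normal((n, 2)) if rng is not None else np.zeros((n, 2))
    if not config.brownian:
        z = np.zeros_like(z)
    dt = np.broadcast_to(np.asarray(dt, dtype=float), (n,))

    pa = _phase_params(particle, fieldf.air, config)
    pm = _phase_params(particle, fieldf.media, config)
    in_media = ens.status[idx] == ACTIVE_MEDIA
    D = np.where(in_media, pm.D, pa.D)
    vs = np.where(in_media, pm.vs, pa.vs)
    tau = np.where(in_media, pm.tau, pa.tau)

    x0 = ens.x[idx]
    y0 = ens.y[idx]
    ufx, ufy = _sample_nodes(fieldf, x0, y0)

    if config.integrator_mode == "overdamped":
        sig = np.sqrt(2.0 * D * dt)
        x1 = x0 + ufx * dt + sig * z[:, 0]
        y1 = y0 + (ufy - vs) * dt + sig * z[:, 1]
    else:
        # Brownian force folded into the target velocity as a constant impulse
        vb = np.sqrt(2.0 * D / dt)[:, None] * z  # F_b / (3 pi mu dp)
        ut = np.column_stack([ufx, ufy - vs]) + vb
        up0 = ens.up[idx]
        if config.drag:
            e = np.exp(-dt / tau)[:, None]
            taud = tau[:, None]
            up1 = ut + (up0 - ut) * e
            disp = ut * dt[:, None] + (up0 - ut) * taud * (1.0 - e)
        else:
            # ballistic: only Brownian + gravity accelerate the particle
            mu_loc = np.where(in_media, pm.mu, pa.mu)
            fb = vb * (3.0 * math.pi * mu_loc * particle.dp)[:, None]
            rho_loc = np.where(in_media, pm.rho, pa.rho)
            g_eff = (
                -(1.0 - rho_loc / particle.rho_p) * config.g if config.gravity else 0.0
            )
            a = fb / particle.mp
            a[:, 1] = a[:, 1] + g_eff
            disp = up0 * dt[:, None] + 0.5 * a * (dt**2)[:, None]
            up1 = up0 + a * dt[:, None]
        ens.up[idx] = up1
        x1 = x0 + disp[:, 0]
        y1 = y0 + disp[:, 1]
    return idx, x1, y1


def apply_boundaries(
    ens: ParticleEnsemble,
    domain: Domain,
    idx: np.ndarray,
    x1: np.ndarray,
    y1: np.ndarray,
    t_new: np.ndarray,
) -> None:
    """Resolve wall/membrane/outlet interactions and commit the step in place.

    Contracts: crossing a membrane-top solid segment deposits the particle at
    the wall; crossing a pore mouth passes it through (phase switches to media
    when it leaves the pore's lower mouth, recording ``t_transfer``); crossing
    the outlet plane records the exit; all other walls reflect specularly.
    Assumes step lengths small relative to the pore width (enforced by the
    tracer's step-size rule), so at most one boundary event per step and axis.
    """
    g = domain.geometry
    ymt = g.y_membrane_top
    hm = g.y_media_top
    H = g.height
    x0 = ens.x[idx]
    y0 = ens.y[idx]
    st = ens.status[idx]
    inertial_up = ens.up  # flipped on reflection to stay specular

    air = st == ACTIVE_AIR
    med = st == ACTIVE_MEDIA

    # --- air phase (channel + pore slots) ---
    if np.any(air):
        ai = idx[air]
        ax0, ay0 = x0[air], y0[air]
        ax1 = x1[air].copy()
        ay1 = y1[air].copy()
        # ceiling and inlet-plane reflections
        hit_top = ay1 > H
        ay1[hit_top] = 2.0 * H - ay1[hit_top]
        np.clip(ay1, None, H - 1e-12, out=ay1)
        hit_in = ax1 < 0.0
        ax1[hit_in] = -ax1[hit_in]
        flip_y = hit_top.copy()
        flip_x = hit_in.copy()

        in_band0 = ay0 < ymt
        # inside a pore slot: reflect off the slot side walls
        if np.any(in_band0):
            k = domain.pore_index(ax0[in_band0])
            a = domain.pore_slots[k, 0]
            bnd = domain.pore_slots[k, 1]
            xx = ax1[in_band0]
            lo = xx < a
            xx[lo] = 2.0 * a[lo] - xx[lo]
            hi = xx > bnd
            xx[hi] = 2.0 * bnd[hi] - xx[hi]
            ax1[in_band0] = np.clip(xx, a + 1e-15, bnd - 1e-15)
            fx = flip_x[in_band0]
            flip_x[in_band0] = fx | lo | hi

        deposited = np.zeros(len(ai), dtype=bool)
        transferred = np.zeros(len(ai), dtype=bool)
        exited = np.zeros(len(ai), dtype=bool)

        # channel particles crossing the membrane-top line
        chan = ~in_band0
        cross = chan & (ay1 < ymt)
        if np.any(cross):
            frac = (ay0[cross] - ymt) / (ay0[cross] - ay1[cross])
            xc = np.clip(ax0[cross] + frac * (ax1[cross] - ax0[cross]), 0.0, g.l)
            pore_hit = domain.in_pore_x(xc)
            dep = cross.copy()
            dep[cross] = ~pore_hit
            deposited |= dep
            ax1[dep] = xc[~pore_hit]
            ay1[dep] = ymt
            ent = cross.copy()
            ent[cross] = pore_hit
            if np.any(ent):
                k = domain.pore_index(xc[pore_hit])
                a = domain.pore_slots[k, 0]
                bnd = domain.pore_slots[k, 1]
                xx = np.clip(ax1[ent], a + 1e-15, bnd - 1e-15)
                ax1[ent] = xx
        transferred = (in_band0 | (cross & ~deposited)) & (ay1 < hm)
        exited = ~deposited & ~transferred & (ax1 >= g.l) & (ay1 >= ymt)

        ens.x[ai] = ax1
        ens.y[ai] = ay1
        ens.t[ai] = t_new[air]
        if np.any(flip_x) or np.any(flip_y):
            inertial_up[ai[flip_x], 0] *= -1.0
            inertial_up[ai[flip_y], 1] *= -1.0
        ens.status[ai[deposited]] = DEPOSITED
        ens.deposit_x[ai[deposited]] = ax1[deposited]
        ens.status[ai[transferred]] = ACTIVE_MEDIA
        ens.t_transfer[ai[transferred]] = t_new[air][transferred]
        ens.status[ai[exited]] = EXITED_AIR
        ens.t_exit_air[ai[exited]] = t_new[air][exited]

    # --- media phase ---
    if np.any(med):
        mi = idx[med]
        mx0, my0 = x0[med], y0[med]
        mx1 = x1[med].copy()
        my1 = y1[med].copy()
        lo = my1 < 0.0
        my1[lo] = -my1[lo]
        hi = my1 > hm
        my1[hi] = 2.0 * hm - my1[hi]
        np.clip(my1, 1e-15, hm - 1e-15, out=my1)
        neg = mx1 < 0.0
        mx1[neg] = -mx1[neg]
        inertial_up[mi[lo | hi], 1] *= -1.0
        inertial_up[mi[neg], 0] *= -1.0

        out = mx1 >= g.l
        if np.any(out):
            frac = np.where(mx1[out] > mx0[out], (g.l - mx0[out]) / (mx1[out] - mx0[out]), 1.0)
            ye = np.clip(my0[out] + frac * (my1[out] - my0[out]), 0.0, hm)
            ens.status[mi[out]] = EXITED_MEDIA
            ens.t_exit[mi[out]] = t_new[med][out]
            ens.y_exit[mi[out]] = ye
            mx1[out] = g.l
            my1[out] = ye
        ens.x[mi] = mx1
        ens.y[mi] = my1
        ens.t[mi] = t_new[med]


def _auto_dt(fieldf: FlowField, domain: Domain, particle, config) -> float:
    g = domain.geometry
    L = g.d / 4.0 if domain.n_pores else min(g.h_air, g.h_media) / 8.0
    pa = _phase_params(particle, fieldf.air, config)
    vmax = max(fieldf.max_speed, pa.vs, 1e-12)
    dt = L / vmax
    if pa.D > 0:
        dt = min(dt, L**2 / (2.0 * pa.D))
    return min(dt, config.max_time / 50.0)


def _media_stride(fieldf: FlowField, domain: Domain, particle, config, dt: float) -> int:
    g = domain.geometry
    Lm = g.h_media / 8.0
    pm = _phase_params(particle, fieldf.media, config)
    med_nodes = fieldf.y_nodes < g.y_media_top
    speed = np.sqrt(fieldf.u[med_nodes, :] ** 2 + fieldf.v[med_nodes, :] ** 2)
    vmax = max(float(speed.max()) if speed.size else 0.0, pm.vs, 1e-12)
    dtm = Lm / vmax
    if pm.D > 0:
        dtm = min(dtm, Lm**2 / (2.0 * pm.D))
    return int(np.clip(math.floor(dtm / dt), 1, 64))


def run_tracing(
    fieldf: FlowField,
    domain: Domain,
    particle: ParticleProperties,
    config: SimulationConfig,
    *,
    keep_ensemble: bool = True,
    observer=None,
) -> SimulationResult:
    """Release, integrate and account for a full particle ensemble.

    Particles start uniformly distributed over the air-channel inlet height
    (``config.release_x`` moves the release plane) with either the local fluid
    velocity or at rest.  Integration proceeds until every particle reaches a
    terminal status or its clock passes ``config.max_time``; unfinished
    particles are flagged incomplete.  Media-phase particles advance with an
    integer-multiple stride of the base step (their geometry and slower flow
    tolerate a coarser step); each particle's Philox substream makes the run
    bit-reproducible for a fixed seed.

    ``observer(ens, t)``, if given, is called after every round of updates
    (used for occupancy sampling in the verification suite).
    """
    g = domain.geometry
    n = config.n_particles
    dt = config.dt if config.dt is not None else _auto_dt(fieldf, domain, particle, config)
    stride_media = _media_stride(fieldf, domain, particle, config, dt)

    master = np.random.Generator(np.random.Philox(key=config.seed))
    ens = ParticleEnsemble.empty(n)
    eps = 1e-3 * g.h_air
    ens.y[:] = g.y_membrane_top + eps + master.random(n) * (g.h_air - 2.0 * eps)
    ens.x[:] = config.release_x if config.release_x is not None else 0.0
    if config.integrator_mode == "inertial" and config.initial_velocity == "fluid":
        ufx, ufy = _sample_nodes(fieldf, ens.x, ens.y)
        ens.up[:, 0] = ufx
        ens.up[:, 1] = ufy

    gens = [
        np.random.Generator(np.random.Philox(key=(int(config.seed) << 32) + pid + 1))
        for pid in range(n)
    ]
    buf = np.empty((n, _RNG_BLOCK, 2))
    ptr = np.full(n, _RNG_BLOCK, dtype=np.int64)

    stride = np.ones(n, dtype=np.int64)
    next_step = np.zeros(n, dtype=np.int64)
    timed_out = np.zeros(n, dtype=bool)

    while True:
        live = ens.active & ~timed_out
        if not live.any():
            break
        s = next_step[live].min()
        due = np.flatnonzero(live & (next_step == s))
        # refill exhausted Brownian buffers
        for i in due[ptr[due] >= _RNG_BLOCK]:
            buf[i] = gens[i].standard_normal((_RNG_BLOCK, 2))
            ptr[i] = 0
        z = buf[due, ptr[due], :]
        ptr[due] += 1
        dt_i = stride[due] * dt
        t_new = ens.t[due] + dt_i
        idx, x1, y1 = step(ens, fieldf, particle, config, dt_i, z=z, idx=due)
        apply_boundaries(ens, domain, idx, x1, y1, t_new)
        # transferred particles switch to the media stride
        stride[due] = np.where(ens.status[due] == ACTIVE_MEDIA, stride_media, stride[due])
        next_step[due] = s + stride[due]
        timed_out |= ens.active & (ens.t >= config.max_time)
        if observer is not None:
            observer(ens, s * dt)

    st = ens.status
    incomplete_air = int(np.sum((st == ACTIVE_AIR) & timed_out))
    incomplete_media = int(np.sum((st == ACTIVE_MEDIA) & timed_out))
    has_transfer = ~np.isnan(ens.t_transfer)
    exited_media = st == EXITED_MEDIA
    return SimulationResult(
        n_released=n,
        deposits=ens.deposit_x[st == DEPOSITED].copy(),
        transfers=ens.t_transfer[has_transfer].copy(),
        media_exit_times=ens.t_exit[exited_media].copy(),
        media_exit_ys=ens.y_exit[exited_media].copy(),
        n_exited_air=int(np.sum(st == EXITED_AIR)),
        n_incomplete_air=incomplete_air,
        n_incomplete_media=incomplete_media,
        complete=(incomplete_air + incomplete_media) == 0,
        dt=dt,
        media_stride=stride_media,
        ensemble=ens if keep_ensemble else None,
    )
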