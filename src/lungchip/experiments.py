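"""End-to-end cases, parametric sweeps, and the verification suite.

``run_case`` composes the full pipeline (domain -> steady flow -> particle
tracing -> metrics) for one parameter set; ``parameter_sweep`` runs the
Cartesian product of particle diameters, pore layouts and inlet velocities,
caching flow solutions per (geometry, fluids, velocities) and writing one CSV
row per case; ``media_injection_case`` swaps the carrier of the top channel
to the media fluid for the aqueous-vs-aerosol comparison.
``verification_suite`` runs the zero-porosity limiting cases: the analytic
plane-Poiseuille profile, a band-concentration decay of 1 um particles under
drag + Brownian forces, depth (in)dependence of the deposition rate with the
shallow-channel drag enabled, and the sedimentation regimes of the
water-carried 1 um and 10 um benchmark particles.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .flow import FlowField, poiseuille_profile, sample_velocity, solve_flow
from .geometry import ChannelGeometry, build_domain
from .metrics import (
    ConcentrationCurve,
    DistributionStats,
    band_concentration,
    concentration_time,
    deposit_distribution,
    deposition_rate,
    outlet_distribution,
    peclet_number,
    transfer_rate,
)
from .particles import SimulationResult, run_tracing
from .properties import (
    FluidProperties,
    ParticleProperties,
    SimulationConfig,
    air_properties,
    media_properties,
)

__all__ = [
    "SweepSpec", "CaseSummary", "FlowCache",
    "run_case", "parameter_sweep", "media_injection_case", "verification_suite",
]


class FlowCache:
    """Memoizes steady flow solutions per (geometry, fluids, velocities, options)."""

    def __init__(self) -> None:
        self._store: dict = {}
        self.hits = 0
        self.misses = 0

    @staticmethod
    def _key(geom, top, bottom, ua, um, shallow, profile, membrane):
        gkey = tuple(
            getattr(geom, k)
            for k in ("h_air", "h_media", "l", "b", "d", "p2p", "porous_x0", "porous_x1")
        )
        fkey = (top.rho, top.mu, top.T, bottom.rho, bottom.mu, bottom.T)
        return (gkey, fkey, float(ua), float(um), shallow, profile, membrane)

    def solve(self, domain, top, bottom, ua, um, shallow=None, profile="uniform",
              membrane="sealed") -> FlowField:
        key = self._key(domain.geometry, top, bottom, ua, um, shallow, profile, membrane)
        if key not in self._store:
            self.misses += 1
            self._store[key] = solve_flow(
                domain, top, bottom, ua, um, shallow,
                inlet_profile=profile, membrane_flow=membrane,
            )
        else:
            self.hits += 1
        return self._store[key]


_default_cache = FlowCache()


@dataclass(frozen=True)
class CaseSummary:
    """One simulated case with its resolved parameters and all summary metrics."""

    dp: float
    rho_p: float
    d: float
    p2p: float
    u_air_inlet: float
    u_media_inlet: float
    n_particles: int
    seed: int
    carrier: str                      # 'air' or 'media' in the top channel
    deposition_rate: float
    transfer_rate: float
    exited_air_fraction: float
    deposition_se: float
    transfer_se: float
    deposit_stats: DistributionStats
    outlet_stats: DistributionStats
    cmax: float
    tmax: float
    incomplete: int
    dt: float
    runtime_s: float = field(default=0.0, compare=False)
    result: SimulationResult | None = field(default=None, repr=False, compare=False)
    curve: ConcentrationCurve | None = field(default=None, repr=False, compare=False)

    def to_row(self) -> dict:
        return {
            "dp_nm": self.dp * 1e9,
            "rho_p": self.rho_p,
            "d_um": self.d * 1e6,
            "p2p_um": self.p2p * 1e6,
            "pore_fraction": 0.0 if self.d == 0 else self.d / (self.d + self.p2p),
            "u_air_mm_s": self.u_air_inlet * 1e3,
            "u_media_mm_s": self.u_media_inlet * 1e3,
            "carrier": self.carrier,
            "n_particles": self.n_particles,
            "seed": self.seed,
            "deposition_rate": self.deposition_rate,
            "transfer_rate": self.transfer_rate,
            "exited_air_fraction": self.exited_air_fraction,
            "deposition_se": self.deposition_se,
            "transfer_se": self.transfer_se,
            "deposit_mean_norm": self.deposit_stats.mean_norm,
            "deposit_std_norm": self.deposit_stats.std_norm,
            "outlet_mean_norm": self.outlet_stats.mean_norm,
            "outlet_std_norm": self.outlet_stats.std_norm,
            "cmax_per_s": self.cmax,
            "tmax_s": self.tmax,
            "incomplete": self.incomplete,
            "dt_s": self.dt,
            "runtime_s": self.runtime_s,
        }


def _binomial_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 0.0) / n)


def run_case(
    geometry: ChannelGeometry,
    particle: ParticleProperties,
    config: SimulationConfig,
    top_fluid: FluidProperties | None = None,
    bottom_fluid: FluidProperties | None = None,
    cache: FlowCache | None = None,
    keep_result: bool = True,
) -> CaseSummary:
    """Solve (or reuse) the flow, trace particles and compute every metric.

    Deterministic per seed: the same inputs give a bit-identical summary.
    """
    top = air_properties() if top_fluid is None else top_fluid
    bottom = media_properties() if bottom_fluid is None else bottom_fluid
    cache = cache or _default_cache
    t0 = time.perf_counter()
    domain = build_domain(geometry)
    fieldf = cache.solve(
        domain, top, bottom, config.u_air_inlet, config.u_media_inlet,
        geometry.depth, config.inlet_profile, config.membrane_flow,
    )
    result = run_tracing(fieldf, domain, particle, config, keep_ensemble=False)
    eps = deposition_rate(result)
    trans = transfer_rate(result)
    curve = concentration_time(result)
    n = result.n_released
    summary = CaseSummary(
        dp=particle.dp, rho_p=particle.rho_p,
        d=geometry.d, p2p=geometry.p2p,
        u_air_inlet=config.u_air_inlet, u_media_inlet=config.u_media_inlet,
        n_particles=n, seed=config.seed,
        carrier="media" if top.rho == bottom.rho and top.mu == bottom.mu else "air",
        deposition_rate=eps, transfer_rate=trans,
        exited_air_fraction=result.n_exited_air / n,
        deposition_se=_binomial_se(eps, n), transfer_se=_binomial_se(trans, n),
        deposit_stats=deposit_distribution(result, geometry.l),
        outlet_stats=outlet_distribution(result, geometry.h_media),
        cmax=curve.cmax, tmax=curve.tmax,
        incomplete=result.n_incomplete_air + result.n_incomplete_media,
        dt=result.dt, runtime_s=time.perf_counter() - t0,
        result=result if keep_result else None,
        curve=curve if keep_result else None,
    )
    return summary


def media_injection_case(
    geometry: ChannelGeometry,
    particle: ParticleProperties,
    config: SimulationConfig,
    cache: FlowCache | None = None,
) -> CaseSummary:
    """Identical pipeline with the top channel carrying the media fluid.

    Emulates injecting the particles as an aqueous suspension instead of an
    aerosol; geometry, gravity direction and all other settings are unchanged.
    """
    m = media_properties()
    return run_case(geometry, particle, config, top_fluid=m, bottom_fluid=m, cache=cache)


@dataclass
class SweepSpec:
    """Axes of a Cartesian parameter sweep.

    ``pore_configs`` are (d, p2p) pairs in meters; ``velocities`` are
    (u_air, u_media) pairs in m/s.  ``replicates`` reruns each case with
    seeds base_seed + r to attach Monte-Carlo error bars.
    """

    dp_values: list
    pore_configs: list
    velocities: list
    replicates: int = 1
    rho_p: float = 1180.0
    base_geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    base_config: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not (self.dp_values and self.pore_configs and self.velocities):
            raise ValueError("sweep axes must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cases(self):
        for dp, (d, p2p), (ua, um), rep in itertools.product(
            self.dp_values, self.pore_configs, self.velocities, range(self.replicates)
        ):
            yield dp, d, p2p, ua, um, rep


_SWEEP_KEY = ["dp_nm", "d_um", "p2p_um", "u_air_mm_s", "u_media_mm_s", "seed"]


def parameter_sweep(
    spec: SweepSpec,
    out_csv=None,
    cache: FlowCache | None = None,
    resume: bool = True,
    carrier: str = "air",
) -> pd.DataFrame:
    """Run the Cartesian product of the sweep axes; one row per case.

    Flow fields are cached per (geometry, velocities).  With ``out_csv`` the
    table is written after every case, and on restart completed cases (matched
    on diameter, pore layout, velocities and seed) are skipped.  A failing
    case is recorded with an ``error`` column instead of aborting the sweep.
    """
    cache = cache or FlowCache()
    done = pd.DataFrame()
    if resume and out_csv is not None:
        try:
            done = pd.read_csv(out_csv)
        except (FileNotFoundError, pd.errors.EmptyDataError):
            done = pd.DataFrame()
    rows = [] if done.empty else done.to_dict("records")

    def _is_done(key_row):
        if done.empty:
            return False
        m = np.ones(len(done), dtype=bool)
        for k, val in key_row.items():
            m &= np.isclose(done[k].to_numpy(dtype=float), val)
        return bool(m.any())

    for dp, d, p2p, ua, um, rep in spec.cases():
        seed = spec.base_config.seed + rep
        key_row = dict(zip(_SWEEP_KEY, [dp * 1e9, d * 1e6, p2p * 1e6, ua * 1e3, um * 1e3, seed]))
        if _is_done(key_row):
            continue
        try:
            geom = replace(spec.base_geometry, d=d, p2p=p2p)
            cfg = spec.base_config.with_(u_air_inlet=ua, u_media_inlet=um, seed=seed)
            part = ParticleProperties(dp=dp, rho_p=spec.rho_p)
            if carrier == "media":
                cs = media_injection_case(geom, part, cfg, cache=cache)
            else:
                cs = run_case(geom, part, cfg, cache=cache, keep_result=False)
            rows.append(cs.to_row())
        except Exception as exc:  # keep sweeping; record the failure
            rows.append({**key_row, "error": repr(exc)})
        if out_csv is not None:
            pd.DataFrame(rows).to_csv(out_csv, index=False)
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


# ---------------------------------------------------------------------------
# verification suite: zero-porosity limiting cases
# ---------------------------------------------------------------------------

def _check(report, name, ok, detail):
    report["checks"].append({"name": name, "passed": bool(ok), **detail})
    if not ok:
        report["passed"] = False


def _single_channel_case(h_top, dp, rho_p, u, seed, n, l=2e-3, mode="overdamped",
                         max_time=600.0):
    """Water-carried particles in a single channel with a sticky floor.

    Realized as the dual-channel device in its impermeable limit (d = 0) with
    the top channel carrying the media fluid and the bottom channel idle.
    """
    geom = ChannelGeometry(h_air=h_top, h_media=50e-6, l=l, d=0.0, p2p=10e-6)
    part = ParticleProperties(dp=dp, rho_p=rho_p)
    cfg = SimulationConfig(
        u_air_inlet=u, u_media_inlet=0.0, n_particles=n, seed=seed,
        integrator_mode=mode, max_time=max_time,
    )
    return media_injection_case(geom, part, cfg)


def verification_suite(seed: int = 0, n_particles: int = 500, fast: bool = True) -> dict:
    """Run and score the limiting-case verifications; returns a JSON-able report.

    (a) mid-channel velocity profile vs. the analytic parallel-plate solution;
    (b) monotone decay of the band-averaged concentration of 1 um particles
        under drag + Brownian forces, plus particle-count accounting
        (run at reduced Peclet so diffusive depletion is measurable);
    (c) deposition rate insensitive to the out-of-plane depth when the
        shallow-channel drag term is enabled;
    (d) sedimentation regimes of the water-carried benchmark particles:
        1 um / 2200 kg m^-3 washed out at 0.3 mm/s but depositing at 0.03 mm/s,
        10 um / 1470 kg m^-3 entrance-concentrated at 0.1 mm/s and spread out
        at 0.3 mm/s.
    """
    report: dict = {"passed": True, "checks": []}

    # (a) Poiseuille profile, impermeable membrane, fully developed inlet
    geom = ChannelGeometry(l=400e-6, d=0.0)
    dom = build_domain(geom)
    ff = solve_flow(dom, air_properties(), media_properties(), 0.3e-3, 0.3e-3,
                    inlet_profile="parabolic")
    y = np.linspace(geom.y_membrane_top, geom.height, 41)[1:-1]
    u_num = sample_velocity(ff, np.full_like(y, geom.l / 2), y)[0]
    u_ref = poiseuille_profile(0.3e-3, geom.h_air, y - geom.y_membrane_top)
    err = float(np.max(np.abs(u_num - u_ref)) / np.max(u_ref))
    _check(report, "poiseuille_profile", err < 0.01, {"max_rel_error": err})

    # (b) band-concentration decay of 1 um particles (drag + Brownian only)
    geom_b = ChannelGeometry(h_air=100e-6, h_media=50e-6, l=2e-3, d=0.0)
    part_b = ParticleProperties(dp=1e-6, rho_p=1180.0)
    u_b = 10e-6
    cfg_b = SimulationConfig(
        u_air_inlet=u_b, u_media_inlet=0.0, n_particles=max(300, n_particles),
        seed=seed, gravity=False, max_time=1200.0,
    )
    dom_b = build_domain(geom_b)
    ff_b = solve_flow(dom_b, air_properties(), media_properties(), u_b, 0.0,
                      inlet_profile="parabolic")
    occupancy: list = []

    def observer(ens, t):
        live = ens.status == 0
        if live.any():
            occupancy.append(ens.x[live].copy())

    res_b = run_tracing(ff_b, dom_b, part_b, cfg_b, observer=observer)
    D_b = part_b.diffusivity(air_properties())
    Pe = peclet_number(u_b, geom_b.h_air, D_b)
    xs = np.concatenate(occupancy) if occupancy else np.array([])
    x_hat, c_hat = band_concentration(xs, geom_b.l, 10, 1e5, geom_b.h_air, Pe)
    third = len(c_hat) // 3
    decays = c_hat[:third].mean() > c_hat[-third:].mean() > 0
    counts = res_b.counts()
    balance = (
        counts["deposited"] + counts["exited_air"]
        + counts["incomplete_air"] + counts["incomplete_media"]
        + counts["transferred"] == counts["released"]
    )
    _check(report, "band_concentration_decay", decays and balance,
           {"profile": c_hat.tolist(), "x_hat": x_hat.tolist(), "counts": counts,
            "peclet": Pe})

    # (c) depth independence of the deposition rate (shallow-channel drag)
    geom_c = ChannelGeometry(l=1e-3, d=0.0)
    part_c = ParticleProperties(dp=900e-9, rho_p=1180.0)
    n_c = max(300, n_particles)
    eps_by_depth = {}
    for depth in (None, 2e-3):
        g_c = replace(geom_c, depth=depth)
        cfg_c = SimulationConfig(u_air_inlet=0.3e-3, u_media_inlet=0.3e-3,
                                 n_particles=n_c, seed=seed, max_time=60.0)
        cs = run_case(g_c, part_c, cfg_c, keep_result=False)
        eps_by_depth["inf" if depth is None else f"{depth:g}"] = cs.deposition_rate
    vals = list(eps_by_depth.values())
    se = math.sqrt(2.0) * _binomial_se(float(np.mean(vals)), n_c)
    ok = abs(vals[0] - vals[1]) <= max(3.0 * se, 0.02)
    _check(report, "depth_independence", ok, {"deposition_rates": eps_by_depth,
                                              "mc_se": se})

    # (d) water-carried benchmark particles (channel length scaled to 2 mm)
    n_d = max(200, n_particles // 2)
    cs_wash = _single_channel_case(100e-6, 1e-6, 2200.0, 0.3e-3, seed, n_d)
    cs_slow = _single_channel_case(100e-6, 1e-6, 2200.0, 0.03e-3, seed, n_d,
                                   max_time=1200.0)
    cs_10a = _single_channel_case(300e-6, 10e-6, 1470.0, 0.1e-3, seed, n_d,
                                  mode="inertial")
    cs_10b = _single_channel_case(300e-6, 10e-6, 1470.0, 0.3e-3, seed, n_d,
                                  mode="inertial")
    # uniform release puts a thin near-floor layer that deposits in the entrance
    # region at any speed, so "washed out" means a small residue, not zero
    washout = (cs_wash.deposition_rate < 0.1
               and cs_wash.deposition_rate < cs_slow.deposition_rate / 4.0)
    slow_dep = cs_slow.deposition_rate > 0.5
    entrance = (
        cs_10a.deposition_rate > 0.9
        and cs_10a.deposit_stats.mean_norm < cs_10b.deposit_stats.mean_norm
    )
    _check(report, "experimental_regimes", washout and slow_dep and entrance, {
        "eps_1um_0.3mm_s": cs_wash.deposition_rate,
        "eps_1um_0.03mm_s": cs_slow.deposition_rate,
        "eps_10um_0.1mm_s": cs_10a.deposition_rate,
        "mean_norm_10um_0.1mm_s": cs_10a.deposit_stats.mean_norm,
        "mean_norm_10um_0.3mm_s": cs_10b.deposit_stats.mean_norm,
    })
    return report
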