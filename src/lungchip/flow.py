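"""Steady incompressible flow in the connected dual-channel domain.

The two channels operate deep in the creeping-flow regime (channel Reynolds
numbers of order 1e-2 to 1e-1 for the default device), so the solver drops
the convective term and solves the steady Stokes equations

    0 = -grad p + mu lap u ,   div u = 0

on a marker-and-cell (MAC) staggered grid with the phase-local viscosity:
media below the membrane, air above it and inside the pore slots.  Boundary
conditions follow the device: prescribed inlet velocity profiles, zero outlet
pressure, and no-slip on every solid-fluid interface (channel walls, membrane
faces, pore side walls).  An optional Hele-Shaw body force -12 mu u / depth^2
approximates a finite out-of-plane depth.  The discrete saddle-point system is
solved directly with a sparse LU factorization; MAC staggering is inf-sup
stable so no pressure stabilization is needed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Domain, GeometryError
from .properties import FluidProperties

__all__ = [
    "FlowField",
    "SolverError",
    "solve_flow",
    "poiseuille_profile",
    "sample_velocity",
    "flow_rate",
    "channel_fluxes",
]


class SolverError(RuntimeError):
    pass


@dataclass
class FlowField:
    """Discrete steady velocity/pressure solution with a continuous sampler.

    ``u``/``v`` are node-collocated (corner) velocity components on the uniform
    grid ``x_nodes`` x ``y_nodes``; nodes on solid boundaries are exactly zero,
    so bilinear interpolation honors no-slip.  The raw staggered face arrays
    are kept for conservative flux bookkeeping.
    """

    domain: Domain
    dx: float
    dy: float
    x_nodes: np.ndarray          # (nx+1,)
    y_nodes: np.ndarray          # (ny+1,)
    u: np.ndarray                # (ny+1, nx+1) node x-velocity
    v: np.ndarray                # (ny+1, nx+1) node y-velocity
    p: np.ndarray                # (ny, nx) cell pressure
    u_face: np.ndarray           # (ny, nx+1)
    v_face: np.ndarray           # (ny+1, nx)
    solid_cell: np.ndarray       # (ny, nx) bool
    media_cell: np.ndarray       # (ny, nx) bool (True below membrane)
    air: FluidProperties = None
    media: FluidProperties = None
    u_air_inlet: float = 0.0
    u_media_inlet: float = 0.0
    shallow_depth: float | None = None
    membrane_flow: str = "sealed"
    residuals: dict = field(default_factory=dict)

    @property
    def nx(self) -> int:
        return len(self.x_nodes) - 1

    @property
    def ny(self) -> int:
        return len(self.y_nodes) - 1

    @property
    def max_speed(self) -> float:
        return float(np.sqrt(self.u**2 + self.v**2).max())

    def divergence(self) -> np.ndarray:
        """Discrete per-cell divergence of the face velocities (zeroed on solid)."""
        div = (self.u_face[:, 1:] - self.u_face[:, :-1]) / self.dx + (
            self.v_face[1:, :] - self.v_face[:-1, :]
        ) / self.dy
        div[self.solid_cell] = 0.0
        return div

    def save(self, path) -> None:
        """Serialize to a self-describing .npz container (arrays + JSON metadata)."""
        g = self.domain.geometry
        meta = {
            "geometry": {k: getattr(g, k) for k in (
                "h_air", "h_media", "l", "b", "d", "p2p", "porous_x0", "porous_x1", "depth")},
            "air": {"rho": self.air.rho, "mu": self.air.mu, "T": self.air.T},
            "media": {"rho": self.media.rho, "mu": self.media.mu, "T": self.media.T},
            "u_air_inlet": self.u_air_inlet,
            "u_media_inlet": self.u_media_inlet,
            "shallow_depth": self.shallow_depth,
            "membrane_flow": self.membrane_flow,
            "residuals": self.residuals,
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            x_nodes=self.x_nodes, y_nodes=self.y_nodes,
            u=self.u, v=self.v, p=self.p,
            u_face=self.u_face, v_face=self.v_face,
            solid_cell=self.solid_cell, media_cell=self.media_cell,
        )

    def profile_table(self, x: float) -> np.ndarray:
        """(y, u, v) samples down a vertical line, for CSV export / plotting."""
        y = self.y_nodes
        uu, vv = sample_velocity(self, np.full_like(y, x), y, validate=False)
        return np.column_stack([y, uu, vv])


def poiseuille_profile(u_mean: float, h: float, y) -> np.ndarray | float:
    """Analytic plane-Poiseuille velocity 6 u_mean y (h - y) / h^2.

    The profile integrates back to ``u_mean`` over [0, h]; y outside [0, h]
    raises ``ValueError``.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0) or np.any(y_arr > h):
        raise ValueError("y outside [0, h]")
    out = 6.0 * u_mean * y_arr * (h - y_arr) / h**2
    return out if out.shape else float(out)


def flow_rate(u_inlet: float, width: float, height: float) -> float:
    """Volumetric flow Q = u * w * h expressed in uL/min."""
    return u_inlet * width * height * 1e9 * 60.0


def _grid_steps(domain: Domain, target_dy: float, nodes_per_pore: int,
                resolve_pores: bool):
    g = domain.geometry
    # dy must divide h_media, b and h_air exactly so that membrane faces land on
    # cell faces; work in integer nanometers to find a common divisor.
    nm = [int(round(s * 1e9)) for s in (g.h_media, g.b, g.h_air)]
    gcd = math.gcd(math.gcd(nm[0], nm[1]), nm[2])
    if gcd == 0:
        raise GeometryError("degenerate geometry: zero-size layer")
    m = max(1, math.ceil(gcd / (target_dy * 1e9)))
    dy = gcd * 1e-9 / m
    if resolve_pores and g.d > 0:
        dx_t = g.d / nodes_per_pore
    else:
        dx_t = max(2.0 * dy, g.l / 200.0)
    nx = max(16, int(round(g.l / dx_t)))
    dx = g.l / nx
    ny = int(round(g.height / dy))
    return nx, ny, dx, dy


def _inlet_profile(kind: str, u_mean: float, y_local: np.ndarray, h: float) -> np.ndarray:
    if kind == "parabolic":
        return 6.0 * u_mean * y_local * (h - y_local) / h**2
    return np.full_like(y_local, u_mean)


def solve_flow(
    domain: Domain,
    air: FluidProperties,
    media: FluidProperties,
    u_air_inlet: float,
    u_media_inlet: float,
    shallow_depth: float | None = None,
    *,
    membrane_flow: str = "sealed",
    inlet_profile: str = "uniform",
    target_dy: float = 2.5e-6,
    nodes_per_pore: int = 6,
    tol: float = 1e-8,
) -> FlowField:
    """Solve the steady Stokes problem and return a :class:`FlowField`.

    Viscosity and density take the local phase's values (media below the
    membrane underside, air elsewhere, pore slots included).  ``shallow_depth``
    switches on the depth-averaged Hele-Shaw drag.  Raises :class:`SolverError`
    if the assembled system cannot be solved to the requested residual.

    ``membrane_flow`` selects the hydraulic treatment of the perforated
    membrane.  ``'sealed'`` (default) closes the pore slots to the *fluid* --
    each channel keeps its imposed flux and the pore interiors are quiescent;
    particles still pass through the pores, driven by gravity and Brownian
    motion.  ``'open'`` resolves the slots as fluid and lets the channels
    exchange flow through them; because the air/media viscosity contrast is
    large, the pore array then short-circuits the channels and most of the
    media inflow is diverted into the air channel near the inlet.
    """
    if membrane_flow not in ("sealed", "open"):
        raise ValueError("membrane_flow must be 'sealed' or 'open'")
    if u_air_inlet < 0 or u_media_inlet < 0:
        raise ValueError("inlet velocities must be >= 0")
    g = domain.geometry
    if shallow_depth is None:
        shallow_depth = g.depth
    nx, ny, dx, dy = _grid_steps(domain, target_dy, nodes_per_pore,
                                 resolve_pores=(membrane_flow == "open"))
    if nx < 2 or ny < 4:
        raise GeometryError("degenerate grid")
    yc = (np.arange(ny) + 0.5) * dy
    xc = (np.arange(nx) + 0.5) * dx
    in_band = (yc >= g.y_media_top) & (yc < g.y_membrane_top)
    pore_col = domain.in_pore_x(xc)
    solid = np.zeros((ny, nx), dtype=bool)
    if membrane_flow == "sealed":
        solid[in_band, :] = True
    else:
        solid[np.ix_(in_band, ~pore_col)] = True
    media_cell = np.zeros((ny, nx), dtype=bool)
    media_cell[yc < g.y_media_top, :] = True
    mu_cell = np.where(media_cell, media.mu, air.mu)

    # inlet u profile per channel (membrane band rows get zero)
    u_in = np.zeros(ny)
    jm = yc < g.y_media_top
    ja = yc > g.y_membrane_top
    u_in[jm] = _inlet_profile(inlet_profile, u_media_inlet, yc[jm], g.h_media)
    u_in[ja] = _inlet_profile(inlet_profile, u_air_inlet, yc[ja] - g.y_membrane_top, g.h_air)

    k_sh = 0.0 if shallow_depth is None else 12.0 / shallow_depth**2

    u_face, v_face, p = _assemble_and_solve(
        nx, ny, dx, dy, solid, mu_cell, u_in, k_sh, tol
    )

    # collocate to nodes; zero every node that touches a solid cell or lies on
    # the floor/ceiling so bilinear sampling respects no-slip exactly there.
    u_node = np.zeros((ny + 1, nx + 1))
    u_node[1:-1, :] = 0.5 * (u_face[:-1, :] + u_face[1:, :])
    v_node = np.zeros((ny + 1, nx + 1))
    v_node[:, 1:-1] = 0.5 * (v_face[:, :-1] + v_face[:, 1:])
    v_node[:, 0] = v_face[:, 0]
    v_node[:, -1] = v_face[:, -1]
    solid_pad = np.zeros((ny + 2, nx + 2), dtype=bool)
    solid_pad[1:-1, 1:-1] = solid
    wall_node = (
        solid_pad[:-1, :-1] | solid_pad[:-1, 1:] | solid_pad[1:, :-1] | solid_pad[1:, 1:]
    )
    wall_node[0, :] = True
    wall_node[-1, :] = True
    u_node[wall_node] = 0.0
    v_node[wall_node] = 0.0

    ff = FlowField(
        domain=domain, dx=dx, dy=dy,
        x_nodes=np.arange(nx + 1) * dx, y_nodes=np.arange(ny + 1) * dy,
        u=u_node, v=v_node, p=p,
        u_face=u_face, v_face=v_face,
        solid_cell=solid, media_cell=media_cell,
        air=air, media=media,
        u_air_inlet=u_air_inlet, u_media_inlet=u_media_inlet,
        shallow_depth=shallow_depth, membrane_flow=membrane_flow,
    )
    scale = max(u_air_inlet, u_media_inlet, 1e-30)
    div_max = float(np.abs(ff.divergence()).max()) * min(dx, dy) / scale
    ff.residuals = {"div_max_normalized": div_max}
    if div_max > max(tol, 1e-7):
        raise SolverError(f"continuity residual {div_max:.3e} exceeds tolerance")
    return ff


def _assemble_and_solve(nx, ny, dx, dy, solid, mu_cell, u_in, k_sh, tol):
    """Assemble the MAC Stokes saddle-point system and solve it directly.

    Unknown layout: u faces (ny, nx+1), v faces (ny+1, nx), cell pressures
    (ny, nx).  Dirichlet rows: inlet u faces, faces touching solid cells
    (vertical solid interfaces are exactly on u-face positions, horizontal
    ones exactly on v-face positions), and solid-cell pressures.  Tangential
    no-slip on horizontal/vertical walls enters through mirror ghosts at half
    a cell, keeping the scheme second order in the clean channel.  The outlet
    u-face momentum uses a zero-gradient ghost velocity and a zero ghost
    pressure, which pins the pressure level of each connected component.
    """
    nu = ny * (nx + 1)
    nv = (ny + 1) * nx
    npp = ny * nx
    ntot = nu + nv + npp

    def uid(j, i):
        return j * (nx + 1) + i

    def vid(j, i):
        return nu + j * nx + i

    def pid(j, i):
        return nu + nv + j * nx + i

    rows, cols, vals = [], [], []
    b = np.zeros(ntot)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    idx2 = 1.0 / dx**2
    idy2 = 1.0 / dy**2

    for j in range(ny):
        for i in range(nx + 1):
            r = uid(j, i)
            if i == 0:
                add(r, r, 1.0)
                b[r] = 0.0 if solid[j, 0] else u_in[j]
                continue
            cl = solid[j, i - 1]
            cr = solid[j, i] if i < nx else False
            if cl or cr:
                add(r, r, 1.0)
                continue
            mu = mu_cell[j, i - 1] if i == nx else 0.5 * (mu_cell[j, i - 1] + mu_cell[j, i])
            diag = -k_sh * mu
            if i == nx:  # outlet: du/dx = 0 ghost, p_ghost = 0
                add(r, uid(j, i - 1), mu * idx2)
                diag -= mu * idx2
                add(r, pid(j, i - 1), 1.0 / dx)
            else:
                add(r, uid(j, i - 1), mu * idx2)
                add(r, uid(j, i + 1), mu * idx2)
                diag -= 2.0 * mu * idx2
                add(r, pid(j, i), -1.0 / dx)
                add(r, pid(j, i - 1), 1.0 / dx)
            for dj in (-1, 1):
                jj = j + dj
                if jj < 0 or jj >= ny or (
                    solid[jj, i - 1] and (solid[jj, i] if i < nx else True)
                ):
                    diag -= 2.0 * mu * idy2  # wall ghost: u_ghost = -u_P
                else:
                    add(r, uid(jj, i), mu * idy2)
                    diag -= mu * idy2
            add(r, r, diag)

    for j in range(ny + 1):
        for i in range(nx):
            r = vid(j, i)
            cb = solid[j - 1, i] if j > 0 else False
            ct = solid[j, i] if j < ny else False
            if j == 0 or j == ny or cb or ct:
                add(r, r, 1.0)
                continue
            mu = 0.5 * (mu_cell[j - 1, i] + mu_cell[j, i])
            diag = -k_sh * mu
            add(r, vid(j - 1, i), mu * idy2)
            add(r, vid(j + 1, i), mu * idy2)
            diag -= 2.0 * mu * idy2
            add(r, pid(j, i), -1.0 / dy)
            add(r, pid(j - 1, i), 1.0 / dy)
            for di in (-1, 1):
                ii = i + di
                if ii < 0:
                    diag -= 2.0 * mu * idx2  # inlet plane: v = 0
                elif ii >= nx:
                    pass  # outlet: dv/dx = 0 ghost
                elif solid[j - 1, ii] and solid[j, ii]:
                    diag -= 2.0 * mu * idx2
                else:
                    add(r, vid(j, ii), mu * idx2)
                    diag -= mu * idx2
            add(r, r, diag)

    for j in range(ny):
        for i in range(nx):
            r = pid(j, i)
            if solid[j, i]:
                add(r, r, 1.0)
                continue
            add(r, uid(j, i + 1), 1.0 / dx)
            add(r, uid(j, i), -1.0 / dx)
            add(r, vid(j + 1, i), 1.0 / dy)
            add(r, vid(j, i), -1.0 / dy)

    A = sp.csc_matrix(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))), shape=(ntot, ntot)
    )
    sol = spla.spsolve(A, b)
    if not np.all(np.isfinite(sol)):
        raise SolverError("direct solve produced non-finite values (singular system?)")
    resid = float(np.max(np.abs(A @ sol - b)))
    # scale by |A| |x| so the check is insensitive to units and grid spacing
    scale = float(np.max(np.abs(A.data))) * max(float(np.max(np.abs(sol))), 1e-300)
    if resid / scale > 1e-8:
        raise SolverError(f"relative linear-system residual {resid/scale:.3e} too large")
    u = sol[:nu].reshape(ny, nx + 1)
    v = sol[nu:nu + nv].reshape(ny + 1, nx)
    p = sol[nu + nv:].reshape(ny, nx)
    return u, v, p


def _sample_nodes(field: FlowField, x, y):
    """Vectorized bilinear interpolation on the node grids (no validation)."""
    nx, ny = field.nx, field.ny
    fx = np.clip(np.asarray(x, dtype=float) / field.dx, 0.0, nx)
    fy = np.clip(np.asarray(y, dtype=float) / field.dy, 0.0, ny)
    i0 = np.minimum(fx.astype(int), nx - 1)
    j0 = np.minimum(fy.astype(int), ny - 1)
    tx = fx - i0
    ty = fy - j0
    u = field.u
    v = field.v
    w00 = (1 - tx) * (1 - ty)
    w10 = tx * (1 - ty)
    w01 = (1 - tx) * ty
    w11 = tx * ty
    uu = (w00 * u[j0, i0] + w10 * u[j0, i0 + 1]
          + w01 * u[j0 + 1, i0] + w11 * u[j0 + 1, i0 + 1])
    vv = (w00 * v[j0, i0] + w10 * v[j0, i0 + 1]
          + w01 * v[j0 + 1, i0] + w11 * v[j0 + 1, i0 + 1])
    return uu, vv


def sample_velocity(field: FlowField, x, y, *, validate: bool = True):
    """Continuous (u, v) at arbitrary points inside the fluid region.

    Bilinear on the uniform node grid: reproduces nodal values exactly at
    nodes and returns (0, 0) on solid boundaries.  With ``validate`` (the
    default), querying a point inside the solid membrane or outside the domain
    raises ``LookupError``.
    """
    from .geometry import SOLID

    if validate:
        cls = field.domain.classify(x, y)
        if np.any(cls == SOLID):
            raise LookupError("query point in solid region or outside the domain")
    return _sample_nodes(field, x, y)


def channel_fluxes(field: FlowField) -> dict:
    """Per-channel volumetric fluxes (per unit depth, m^2/s) and pore exchange.

    ``pore_down`` is the net downward flow through the membrane-top plane;
    global conservation requires inlet = outlet + net pore loss per channel.
    """
    g = field.domain.geometry
    yc = (np.arange(field.ny) + 0.5) * field.dy
    jm = yc < g.y_media_top
    ja = yc > g.y_membrane_top
    dy = field.dy
    j_top = int(round(g.y_membrane_top / dy))
    j_bot = int(round(g.y_media_top / dy))
    out = {
        "air_in": float(field.u_face[ja, 0].sum() * dy),
        "air_out": float(field.u_face[ja, -1].sum() * dy),
        "media_in": float(field.u_face[jm, 0].sum() * dy),
        "media_out": float(field.u_face[jm, -1].sum() * dy),
        "pore_down_top": -float(field.v_face[j_top, :].sum() * field.dx),
        "pore_down_bottom": -float(field.v_face[j_bot, :].sum() * field.dx),
    }
    out["net_pore_flux"] = out["pore_down_top"]
    return out
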