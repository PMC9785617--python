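"""Shared fixtures: small solved flow fields and diffusion oracles."""

import math

import numpy as np
import pytest

import lungchip as lc


def assert_summary_equal(a, b):
    """Bit-equality of two CaseSummary rows, treating NaN == NaN."""
    ra, rb = a.to_row(), b.to_row()
    assert ra.keys() == rb.keys()
    for k in ra:
        if k == "runtime_s":
            continue
        va, vb = ra[k], rb[k]
        if isinstance(va, float) and math.isnan(va):
            assert math.isnan(vb), k
        else:
            assert va == vb, k


@pytest.fixture(scope="session")
def small_geometry():
    """Short dual-channel device: 200 um long, d = p2p = 10 um."""
    return lc.ChannelGeometry(l=200e-6, d=10e-6, p2p=10e-6)


@pytest.fixture(scope="session")
def small_domain(small_geometry):
    return lc.build_domain(small_geometry)


@pytest.fixture(scope="session")
def small_field(small_domain):
    """Sealed-membrane steady field at the reference 0.3 mm/s inlets."""
    return lc.solve_flow(
        small_domain, lc.air_properties(), lc.media_properties(), 0.3e-3, 0.3e-3
    )


@pytest.fixture(scope="session")
def small_field_open(small_domain):
    """Connected-domain (pores open to flow) variant of the small field."""
    return lc.solve_flow(
        small_domain, lc.air_properties(), lc.media_properties(), 0.3e-3, 0.3e-3,
        membrane_flow="open",
    )


@pytest.fixture(scope="session")
def still_box():
    """Quiescent fluid box (zero inlets) for pure Brownian / settling checks.

    A tall impermeable-membrane device; the air channel acts as the box, its
    floor (the membrane top) is the absorbing wall and its ceiling reflects.
    """
    geom = lc.ChannelGeometry(h_air=100e-6, h_media=50e-6, l=2e-3, d=0.0)
    dom = lc.build_domain(geom)
    ff = lc.solve_flow(dom, lc.air_properties(), lc.media_properties(), 0.0, 0.0)
    return geom, dom, ff


def absorbed_fraction_fd(D, h, times, eps_frac=1e-3, n_grid=400):
    """1D diffusion between an absorbing floor (y=0) and reflecting ceiling (y=h).

    Crank-Nicolson oracle for the absorbed fraction versus time, starting from
    a uniform concentration on [eps, h - eps] (matching the tracer's release
    margin).  Independent of the Lagrangian implementation it checks.
    """
    y = np.linspace(0.0, h, n_grid + 1)
    dy = y[1] - y[0]
    c = np.ones(n_grid + 1)
    eps = eps_frac * h
    c[y < eps] = 0.0
    c[y > h - eps] = 0.0
    c[0] = 0.0
    mass0 = np.trapezoid(c, y)
    dt = (h**2 / D) / 8000.0  # CN is unconditionally stable; error O(dt^2)
    r = D * dt / (2 * dy**2)
    n = n_grid + 1
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    main = np.full(n, 1 + 2 * r)
    lower = np.full(n - 1, -r)
    upper = np.full(n - 1, -r)
    main[0] = 1.0       # absorbing at y=0
    upper[0] = 0.0
    lower[-1] = -2 * r  # reflecting at y=h (mirror ghost)
    A = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
    Bmain = np.full(n, 1 - 2 * r)
    Blower = np.full(n - 1, r)
    Bupper = np.full(n - 1, r)
    Bmain[0] = 0.0
    Bupper[0] = 0.0
    Blower[-1] = 2 * r
    B = sp.diags([Blower, Bmain, Bupper], [-1, 0, 1], format="csc")
    solve = spla.factorized(A)
    out = []
    t = 0.0
    for target in sorted(times):
        while t < target - 1e-12:
            c = solve(B @ c)
            c[0] = 0.0
            t += dt
        out.append(1.0 - np.trapezoid(c, y) / mass0)
    return dict(zip(sorted(times), out))
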