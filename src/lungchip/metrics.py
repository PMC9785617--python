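"""Summary statistics of deposition, translocation and dispersion.

Definitions follow the device conventions: the deposition rate is the
fraction of released particles stuck to the membrane-top substrate of the air
channel; the transfer (translocation) rate is the fraction that passed
through membrane pores into the media channel.  Positions are reported
normalized -- deposit x by the channel length, outlet y by the media-channel
height measured from its floor (membrane side = 1).  A uniform deposition has
normalized mean 1/2 and standard deviation 1/sqrt(12); those exact moments
are the "ideal" reference lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .particles import SimulationResult

__all__ = [
    "DistributionStats",
    "ConcentrationCurve",
    "deposition_rate",
    "transfer_rate",
    "deposit_distribution",
    "outlet_distribution",
    "band_concentration",
    "peclet_number",
    "concentration_time",
    "UNIFORM_MEAN",
    "UNIFORM_STD",
]

UNIFORM_MEAN = 0.5
UNIFORM_STD = 1.0 / np.sqrt(12.0)


class UndefinedRateError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class DistributionStats:
    """Mean and population standard deviation of a normalized position sample."""

    mean_norm: float
    std_norm: float
    n: int

    @property
    def empty(self) -> bool:
        return self.n == 0


def _rate(count: int, result: SimulationResult) -> float:
    if result.n_released <= 0:
        raise UndefinedRateError("no particles released")
    return count / result.n_released


def deposition_rate(result: SimulationResult) -> float:
    """Deposited fraction: |deposits| / n_released, in [0, 1]."""
    return _rate(result.n_deposited, result)


def transfer_rate(result: SimulationResult) -> float:
    """Translocated fraction: |transfers| / n_released, in [0, 1]."""
    return _rate(result.n_transferred, result)


def _stats(values: np.ndarray, scale: float) -> DistributionStats:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return DistributionStats(mean_norm=float("nan"), std_norm=float("nan"), n=0)
    z = values / scale
    return DistributionStats(
        mean_norm=float(z.mean()), std_norm=float(z.std()), n=int(z.size)
    )


def deposit_distribution(result: SimulationResult, l: float) -> DistributionStats:
    """Moments of deposit positions x/l.  Zero deposits yields an empty (NaN) record."""
    return _stats(result.deposits, l)


def outlet_distribution(result: SimulationResult, h_media: float) -> DistributionStats:
    """Moments of media-outlet crossing heights y/h, floor = 0, membrane side = 1."""
    return _stats(result.media_exit_ys, h_media)


def peclet_number(u_mean: float, h: float, D: float) -> float:
    """Channel Peclet number Pe = 2 u h / D (convection over diffusion)."""
    return 2.0 * u_mean * h / D


def band_concentration(
    positions,
    l: float,
    n_bands: int,
    C0: float,
    h: float,
    Pe: float,
):
    """Band-averaged particle concentration along the channel, normalized.

    The channel is partitioned into ``n_bands`` equal bands; each band's count
    is divided by the band measure (band length x channel height, unit depth)
    and by the reference areal concentration ``C0``.  Returns
    ``(x_hat, c_hat)`` where the band centers are normalized by the
    convection-diffusion length 3 h Pe / 16.

    ``positions`` may be a multiset (e.g. occupancy samples accumulated over
    time); empty bands simply read zero.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    positions = np.asarray(positions, dtype=float)
    if positions.size and (positions.min() < 0 or positions.max() > l):
        raise ValueError("positions must lie in [0, l]")
    counts, edges = np.histogram(positions, bins=n_bands, range=(0.0, l))
    band_len = l / n_bands
    conc = counts / (band_len * h) / C0
    centers = 0.5 * (edges[:-1] + edges[1:])
    x_scale = 3.0 * h * Pe / 16.0
    return centers / x_scale, conc


def _gaussian(t, A, t0, w):
    return A * np.exp(-((t - t0) ** 2) / (2.0 * w**2))


@dataclass
class ConcentrationCurve:
    """Relative concentration of transferred particles at the media outlet.

    ``c_cum(t)`` is the cumulative fraction of *released* particles that have
    left through the media outlet by time t (non-decreasing, bounded by the
    transfer rate); ``c_rate`` its central-difference time derivative.  A
    Gaussian A exp(-(t - tmax)^2 / (2 w^2)) is least-squares fitted to the
    rate; ``cmax``/``tmax`` are the fitted peak value and peak time.  Runs
    with fewer than 5 exits keep the raw curve with ``fit_ok = False``.
    """

    t: np.ndarray
    c_cum: np.ndarray
    c_rate: np.ndarray
    fit_ok: bool = False
    amplitude: float = float("nan")
    center: float = float("nan")
    width: float = float("nan")

    @property
    def cmax(self) -> float:
        if self.fit_ok:
            return self.amplitude
        return 0.0 if not np.any(self.c_rate) else float(np.max(self.c_rate))

    @property
    def tmax(self) -> float:
        if self.fit_ok:
            return self.center
        if not np.any(self.c_rate):
            return float("nan")
        return float(self.t[int(np.argmax(self.c_rate))])

    def area(self) -> float:
        """Trapezoid area under the rate curve (equals the exited fraction)."""
        return float(np.trapezoid(self.c_rate, self.t))


def concentration_time(
    result: SimulationResult,
    t_grid: np.ndarray | None = None,
    n_bins: int = 200,
) -> ConcentrationCurve:
    """Build the concentration-time curve from the media-exit records.

    Default grid: ``n_bins`` uniform points spanning the first to last exit
    (padded by one bin on each side so the rate returns to zero, which keeps
    the numerical differentiation and the Gaussian fit stable).
    """
    te = np.sort(np.asarray(result.media_exit_times, dtype=float))
    n_rel = result.n_released
    if te.size == 0:
        t = np.linspace(0.0, 1.0, 8) if t_grid is None else np.asarray(t_grid, float)
        zero = np.zeros_like(t)
        return ConcentrationCurve(t=t, c_cum=zero, c_rate=zero.copy(), fit_ok=False)
    if t_grid is None:
        span = max(te[-1] - te[0], te[-1] * 1e-3, 1e-9)
        pad = span / n_bins
        t_grid = np.linspace(max(te[0] - pad, 0.0), te[-1] + pad, n_bins)
    t = np.asarray(t_grid, dtype=float)
    c_cum = np.searchsorted(te, t, side="right") / n_rel
    c_rate = np.gradient(c_cum, t)
    curve = ConcentrationCurve(t=t, c_cum=c_cum, c_rate=c_rate)
    if te.size < 5:
        return curve
    # least-squares Gaussian fit, initialized from the raw peak
    k = int(np.argmax(c_rate))
    p0 = (max(c_rate[k], 1e-12), t[k], max((te[-1] - te[0]) / 4.0, 1e-9))
    try:
        popt, _ = curve_fit(
            _gaussian, t, c_rate, p0=p0,
            bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        curve.fit_ok = True
        curve.amplitude, curve.center, curve.width = map(float, popt)
    except (RuntimeError, ValueError):
        curve.fit_ok = False
    return curve
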