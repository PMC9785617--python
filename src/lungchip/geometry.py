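"""Dual-channel + perforated-membrane geometry.

The device is modeled in 2D (x streamwise, y vertical): a media channel of
height ``h_media`` at the bottom, a membrane band of thickness ``b`` above it,
and an air channel of height ``h_air`` on top.  Cylindrical membrane pores
become through-slots of width ``d`` spanning the membrane thickness -- the 2D
analogue of the real perforation.  Slots tile the porous region left to right
with period ``d + p2p``, where ``p2p`` is the edge-to-edge pore spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ChannelGeometry", "Domain", "build_domain", "GeometryError",
           "AIR", "MEDIA", "PORE", "SOLID"]


class GeometryError(ValueError):
    pass


# point-classification codes
AIR = 0
MEDIA = 1
PORE = 2
SOLID = 3


@dataclass(frozen=True)
class ChannelGeometry:
    """Layout of the dual-channel device (all lengths in meters).

    ``d = 0`` encodes an impermeable membrane (the zero-porosity limiting
    cases).  ``depth`` is the optional out-of-plane channel depth used by the
    shallow-channel (Hele-Shaw) drag correction; ``None`` means effectively
    infinite depth, i.e. a strictly 2D flow.
    """

    h_air: float = 100e-6
    h_media: float = 100e-6
    l: float = 2e-3
    b: float = 10e-6
    d: float = 10e-6
    p2p: float = 10e-6
    porous_x0: float = 0.0
    porous_x1: float | None = None
    depth: float | None = None

    def __post_init__(self) -> None:
        for name in ("h_air", "h_media", "l", "b"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"ChannelGeometry.{name} must be > 0")
        if self.d < 0:
            raise GeometryError("pore diameter d must be >= 0")
        if self.d > 0 and self.p2p <= 0:
            raise GeometryError("pore spacing p2p must be > 0 when d > 0")
        if self.depth is not None and self.depth <= 0:
            raise GeometryError("depth must be > 0 when set")
        x1 = self.l if self.porous_x1 is None else self.porous_x1
        if not (0.0 <= self.porous_x0 < x1 <= self.l):
            raise GeometryError("need 0 <= porous_x0 < porous_x1 <= l")
        if self.d > 0 and self.n_pores < 1:
            raise GeometryError("porous region too short: no full pore fits")

    @property
    def porous_extent(self) -> tuple[float, float]:
        return (self.porous_x0, self.l if self.porous_x1 is None else self.porous_x1)

    @property
    def pore_period(self) -> float:
        return self.d + self.p2p

    @property
    def n_pores(self) -> int:
        if self.d == 0:
            return 0
        x0, x1 = self.porous_extent
        return int(math.floor((x1 - x0 + self.p2p) / self.pore_period + 1e-12))

    @property
    def pore_area_fraction(self) -> float:
        """Open fraction of the porous region, d / (d + p2p)."""
        return 0.0 if self.d == 0 else self.d / self.pore_period

    @property
    def y_media_top(self) -> float:
        """y of the membrane underside (media-channel ceiling)."""
        return self.h_media

    @property
    def y_membrane_top(self) -> float:
        """y of the membrane top (air-channel floor; the sticky substrate)."""
        return self.h_media + self.b

    @property
    def height(self) -> float:
        return self.h_media + self.b + self.h_air


class Domain:
    """Connected 2D fluid region derived from a :class:`ChannelGeometry`.

    Provides vectorized point classification and the boundary-segment
    bookkeeping the particle tracer needs: membrane-top solid segments are the
    sticky (absorbing) substrate, pore mouths are pass-through interfaces.
    """

    def __init__(self, geom: ChannelGeometry):
        self.geometry = geom
        x0, x1 = geom.porous_extent
        n = geom.n_pores
        starts = x0 + np.arange(n) * geom.pore_period
        self.pore_slots = np.column_stack([starts, starts + geom.d]) if n else np.empty((0, 2))

    @property
    def n_pores(self) -> int:
        return len(self.pore_slots)

    def in_pore_x(self, x) -> np.ndarray:
        """True where streamwise position x falls inside a pore slot."""
        x = np.asarray(x, dtype=float)
        g = self.geometry
        if g.d == 0:
            return np.zeros(x.shape, dtype=bool)
        x0, _ = g.porous_extent
        off = x - x0
        k = np.floor(off / g.pore_period)
        rem = off - k * g.pore_period
        return (off >= 0) & (k < self.n_pores) & (rem <= g.d)

    def pore_index(self, x) -> np.ndarray:
        """Slot index for positions inside pores (undefined elsewhere)."""
        g = self.geometry
        x = np.asarray(x, dtype=float)
        return np.clip(
            np.floor((x - g.porous_x0) / g.pore_period).astype(int), 0, max(self.n_pores - 1, 0)
        )

    def classify(self, x, y) -> np.ndarray:
        """Classify points as AIR, MEDIA, PORE or SOLID (vectorized).

        The partition uses half-open conventions so every in-domain point maps
        to exactly one class; points outside [0,l] x [0,height] are SOLID.
        """
        g = self.geometry
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(np.broadcast(x, y).shape, SOLID, dtype=np.int8)
        inside_x = (x >= 0) & (x <= g.l)
        out[inside_x & (y >= g.y_membrane_top) & (y <= g.height)] = AIR
        out[inside_x & (y >= 0) & (y < g.y_media_top)] = MEDIA
        band = inside_x & (y >= g.y_media_top) & (y < g.y_membrane_top)
        out[band & self.in_pore_x(x)] = PORE
        return out

    def membrane_top_segments(self) -> list[tuple[float, float]]:
        """Solid spans of the membrane-top line (the sticky substrate)."""
        g = self.geometry
        if self.n_pores == 0:
            return [(0.0, g.l)]
        segs = []
        prev = 0.0
        for a, bnd in self.pore_slots:
            if a > prev:
                segs.append((prev, float(a)))
            prev = float(bnd)
        if prev < g.l:
            segs.append((prev, g.l))
        return segs

    def pore_mouth_segments(self) -> list[tuple[float, float]]:
        """Open spans of the membrane-top line (pass-through pore mouths)."""
        return [tuple(map(float, s)) for s in self.pore_slots]


def build_domain(geom: ChannelGeometry) -> Domain:
    """Validate the layout and return the connected :class:`Domain`.

    Raises :class:`GeometryError` when pores overlap or extend beyond the
    porous region.
    """
    dom = Domain(geom)
    if dom.n_pores:
        x0, x1 = geom.porous_extent
        if dom.pore_slots[-1, 1] > x1 + 1e-12:
            raise GeometryError("pore slots extend beyond the porous region")
        gaps = dom.pore_slots[1:, 0] - dom.pore_slots[:-1, 1]
        if len(gaps) and gaps.min() < -1e-15:
            raise GeometryError("pore slots overlap")
    return dom
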