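"""Multi-dimensional decoding and zooming display geometry.

A 2D (or N-D) selection runs one independent decoder per axis; the joint
belief is the product of the marginals, and input is requested for the axis
with the most remaining uncertainty.  The diagonal-split mapping renders
every query as a left/right decision regardless of axis, so a two-state
input never changes meaning.

Display transforms: the linear zoom viewport frames the highest-density
posterior intervals (HDPI) of both axes at fixed aspect ratio, and the
nonlinear warp stretches screen space in proportion to posterior mass (the
probability-integral transform), pushing unlikely regions to the edges.
All operations here are pure geometry — no rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import decoder as hd

__all__ = [
    "MultiDecoder",
    "Viewport",
    "TargetLayout",
    "schedule_axis",
    "diagonal_decision",
    "hdpi",
    "linear_viewport",
    "nonlinear_warp",
    "layout_targets",
]


@dataclass
class MultiDecoder:
    """Independent per-axis decoders; the joint density is their product."""

    axes: list[hd.DecoderState]

    @classmethod
    def create(cls, configs: Sequence[hd.DecoderConfig]) -> "MultiDecoder":
        return cls([hd.init_decoder(c) for c in configs])

    @property
    def n_axes(self) -> int:
        return len(self.axes)

    def terminated(self) -> bool:
        return all(hd.is_terminated(s) for s in self.axes)

    def decode(self) -> tuple[int, ...]:
        return tuple(hd.decode_symbol(s) for s in self.axes)


def schedule_axis(md: MultiDecoder) -> int:
    """Unterminated axis with the largest remaining entropy (ties: lowest index)."""
    best, best_h = None, -math.inf
    for i, s in enumerate(md.axes):
        if hd.is_terminated(s):
            continue
        h = hd.entropy(s)
        if h > best_h:
            best, best_h = i, h
    if best is None:
        raise ValueError("all axes are terminated")
    return best


def diagonal_decision(md: MultiDecoder, target: Sequence[float]) -> tuple[int, int]:
    """Axis to query and the oracle's left/right bit for it.

    On screen the scheduled axis's median is always drawn as a left/right
    divider (the grid is rotated 45 degrees), so the answer is a pure
    left/right choice whichever axis is active.  No state is changed.
    """
    axis = schedule_axis(md)
    b = 0 if target[axis] < hd.median(md.axes[axis]) else 1
    return axis, b


def hdpi(state: hd.DecoderState, coverage: float) -> tuple[float, float]:
    """Shortest interval holding at least ``coverage`` posterior mass.

    Computed exactly on the piecewise density: the interval is
    ``[Q(u), Q(u + coverage)]`` minimised over ``u``, and the minimum is
    attained with an endpoint at a CDF breakpoint, so only breakpoint
    candidates need be swept.  Ties are broken leftmost.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    cdf = state.cdf
    cands = np.unique(np.clip(np.concatenate([cdf.F, cdf.F - coverage]),
                              0.0, 1.0 - coverage))
    best = None
    for u in cands:
        lo = cdf.quantile(float(u))
        hi = cdf.quantile(float(u) + coverage)
        length = hi - lo
        if best is None or length < best[0] - 1e-15:
            best = (length, lo, hi)
    return best[1], best[2]


@dataclass(frozen=True)
class Viewport:
    """Square view of the unit square: centre and half-width."""

    cx: float
    cy: float
    half_width: float

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.cx - self.half_width, self.cy - self.half_width,
                self.cx + self.half_width, self.cy + self.half_width)

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.bounds
        return x0 <= x <= x1 and y0 <= y <= y1


def linear_viewport(md: MultiDecoder, coverage: float = 0.5) -> Viewport:
    """Smallest square spanning both axes' HDPIs, clamped to the unit square.

    Aspect ratio is preserved by taking the larger of the two HDPI lengths
    as the side; the centre follows the HDPI centres, shifted as needed to
    keep the view inside [0, 1]^2.
    """
    if md.n_axes != 2:
        raise ValueError(f"linear_viewport needs a 2D decoder, got {md.n_axes} axes")
    (x0, x1) = hdpi(md.axes[0], coverage)
    (y0, y1) = hdpi(md.axes[1], coverage)
    half = 0.5 * max(x1 - x0, y1 - y0)
    cx = min(max(0.5 * (x0 + x1), half), 1.0 - half)
    cy = min(max(0.5 * (y0 + y1), half), 1.0 - half)
    return Viewport(cx=cx, cy=cy, half_width=half)


def nonlinear_warp(state: hd.DecoderState, x: float) -> float:
    """Warp a world coordinate to display space via the posterior CDF.

    Equal display space per unit posterior mass: dense regions stretch,
    unlikely regions squash toward the edges.  Monotone, with fixed
    endpoints, and the median always maps to 0.5.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"coordinate must be in [0, 1], got {x}")
    return state.cdf.cdf(x)


@dataclass(frozen=True)
class TargetLayout:
    """Consecutive half-open intervals tiling [0, 1] with prior-sized widths."""

    boundaries: tuple[float, ...]  # n+1 values, 0 .. 1

    @property
    def n(self) -> int:
        return len(self.boundaries) - 1

    def interval(self, s: int) -> tuple[float, float]:
        return self.boundaries[s], self.boundaries[s + 1]

    def width(self, s: int) -> float:
        lo, hi = self.interval(s)
        return hi - lo

    def decode(self, point: float) -> int:
        """Index of the half-open interval containing ``point`` (1.0 -> last)."""
        if not 0.0 <= point <= 1.0:
            raise ValueError(f"point must be in [0, 1], got {point}")
        i = int(np.searchsorted(self.boundaries, point, side="right")) - 1
        return min(i, self.n - 1)


def layout_targets(prior: Sequence[float]) -> TargetLayout:
    """Lay targets on the interval with widths proportional to prior mass.

    A uniform prior over 2^k targets reproduces the ``floor(2^k * m)``
    decode rule.
    """
    masses = np.asarray(prior, dtype=float)
    if masses.ndim != 1 or masses.size == 0:
        raise ValueError("prior must be a non-empty 1D sequence")
    if np.any(masses <= 0.0):
        raise ValueError("prior masses must be positive")
    b = np.concatenate([[0.0], np.cumsum(masses / masses.sum())])
    b[-1] = 1.0
    return TargetLayout(boundaries=tuple(float(v) for v in b))
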