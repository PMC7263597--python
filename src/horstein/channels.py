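"""Noisy binary channel models and their information-theoretic bounds.

An input device that produces two states which are randomly flipped is
modelled as a binary channel with flip probabilities ``f0 = P(0 -> 1)`` and
``f1 = P(1 -> 0)``.  When ``f0 == f1`` this is the binary symmetric channel;
otherwise it is a biased (Z-type) channel.  Temporally correlated ("bursty")
noise is modelled by a two-state Gilbert-Elliott Markov chain that switches
between a good and a bad state with different flip probabilities.

Capacities are expressed in bits per binary input; their reciprocal is the
number of input decisions a user must produce per error-free output bit,
which is the natural figure of merit for interface design.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "BinaryChannelSpec",
    "GilbertElliotSpec",
    "ChannelState",
    "binary_entropy",
    "capacity_bsc",
    "capacity_bac",
    "rate_bound",
    "transmit",
    "make_gilbert_elliot",
    "ge_step",
    "BernoulliChannel",
    "GilbertElliotChannel",
    "channel_from_json",
]


def binary_entropy(f: float) -> float:
    """Binary entropy H(f) in bits, with the limit x*log2(x) -> 0 at x=0."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"probability out of range: {f}")
    if f == 0.0 or f == 1.0:
        return 0.0
    return -f * math.log2(f) - (1.0 - f) * math.log2(1.0 - f)


@dataclass(frozen=True)
class BinaryChannelSpec:
    """Memoryless binary channel with flip probabilities ``f0`` and ``f1``.

    ``f0`` is the probability that an intended 0 is received as 1, ``f1``
    that an intended 1 is received as 0.  Derived quantities: mean error
    ``f = (f0 + f1)/2``, absolute bias ``f_delta`` with ``f0 = f + f_delta``
    and ``f1 = f - f_delta``, and relative bias ``b = f_delta / f``
    (undefined, returned as NaN, for a noise-free channel).
    """

    f0: float
    f1: float

    def __post_init__(self) -> None:
        for name in ("f0", "f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def f(self) -> float:
        return 0.5 * (self.f0 + self.f1)

    @property
    def f_delta(self) -> float:
        return 0.5 * (self.f0 - self.f1)

    @property
    def bias(self) -> float:
        if self.f == 0.0:
            return float("nan")
        return self.f_delta / self.f

    @classmethod
    def from_mean_bias(cls, f: float, b: float) -> "BinaryChannelSpec":
        """Build a spec from mean error rate ``f`` and relative bias ``b``."""
        return cls(f0=f + b * f, f1=f - b * f)

    def to_json(self) -> dict:
        return {"f0": self.f0, "f1": self.f1}

    @classmethod
    def from_json(cls, obj: dict) -> "BinaryChannelSpec":
        return cls(f0=float(obj["f0"]), f1=float(obj["f1"]))


def capacity_bsc(f: float) -> float:
    """Capacity of the binary symmetric channel, 1 - H(f), in bits/input."""
    return 1.0 - binary_entropy(f)


def _canonicalise(f0: float, f1: float) -> tuple[float, float]:
    # Relabelling output bits maps (f0, f1) -> (1-f0, 1-f1); relabelling the
    # input maps (f0, f1) -> (f1, f0).  Neither changes capacity, so reduce
    # to f0 <= f1 and f0 + f1 <= 1 before applying the closed form.
    if f0 + f1 > 1.0:
        f0, f1 = 1.0 - f0, 1.0 - f1
    if f0 > f1:
        f0, f1 = f1, f0
    return f0, f1


def capacity_bac(spec_or_f0: Union[BinaryChannelSpec, float], f1: float | None = None) -> float:
    """Capacity of the binary asymmetric channel in bits per input.

    Accepts either a :class:`BinaryChannelSpec` or the pair ``(f0, f1)``.
    The 0/1 labels are swapped internally so the closed form's preconditions
    hold; callers never see relabelled bits.  Degenerate channels with
    ``f0 + f1 = 1`` (output independent of input) have capacity 0.
    """
    if isinstance(spec_or_f0, BinaryChannelSpec):
        f0, f1 = spec_or_f0.f0, spec_or_f0.f1
    else:
        if f1 is None:
            raise TypeError("capacity_bac requires a spec or both f0 and f1")
        f0 = float(spec_or_f0)
    if not (0.0 <= f0 <= 1.0 and 0.0 <= f1 <= 1.0):
        raise ValueError(f"flip probabilities out of [0, 1]: f0={f0}, f1={f1}")
    f0, f1 = _canonicalise(f0, f1)
    fd = 1.0 - f0 - f1
    if fd == 0.0:
        return 0.0
    if f0 == f1:
        return capacity_bsc(f0)
    h0 = binary_entropy(f0)
    h1 = binary_entropy(f1)
    c = (f0 / fd) * h1 - ((1.0 - f1) / fd) * h0 + math.log2(1.0 + 2.0 ** ((h0 - h1) / fd))
    # Clamp tiny negative round-off near zero-capacity channels.
    return max(c, 0.0)


def rate_bound(spec_or_f0: Union[BinaryChannelSpec, float], f1: float | None = None) -> float:
    """Minimum input decisions per error-free bit, 1/capacity.

    Returns ``+inf`` for a zero-capacity channel.
    """
    c = capacity_bac(spec_or_f0, f1)
    if c <= 0.0:
        return float("inf")
    return 1.0 / c


def transmit(intended_bit: int, spec: BinaryChannelSpec, rng: np.random.Generator) -> int:
    """Pass one bit through the memoryless channel."""
    if intended_bit == 0:
        return 1 if rng.random() < spec.f0 else 0
    if intended_bit == 1:
        return 0 if rng.random() < spec.f1 else 1
    raise ValueError(f"bit must be 0 or 1, got {intended_bit}")


# ---------------------------------------------------------------------------
# Gilbert-Elliott bursty channel
# ---------------------------------------------------------------------------

GOOD, BAD = 0, 1


@dataclass(frozen=True)
class GilbertElliotSpec:
    """Two-state Markov noise process.

    ``p_b`` is the per-step probability of entering the bad state, ``p_g``
    of leaving it.  Flip probabilities are ``f_G`` in the good state and
    ``f_B`` in the bad state (defaults 0 and 1).  ``f`` is the target mean
    error rate and ``t`` the burstiness (mean dwell steps in the bad state).
    """

    f: float
    t: float
    p_b: float
    p_g: float
    f_G: float = 0.0
    f_B: float = 1.0

    @property
    def stationary_bad(self) -> float:
        return self.p_b / (self.p_b + self.p_g)

    @property
    def mean_error(self) -> float:
        pi_b = self.stationary_bad
        return (1.0 - pi_b) * self.f_G + pi_b * self.f_B

    def to_json(self) -> dict:
        return {"model": "gilbert_elliot", "f": self.f, "t": self.t,
                "f_G": self.f_G, "f_B": self.f_B}

    @classmethod
    def from_json(cls, obj: dict) -> "GilbertElliotSpec":
        return make_gilbert_elliot(float(obj["f"]), float(obj["t"]),
                                   f_G=float(obj.get("f_G", 0.0)),
                                   f_B=float(obj.get("f_B", 1.0)))


@dataclass
class ChannelState:
    """Current Markov state of a Gilbert-Elliott channel."""

    state: int = GOOD  # GOOD or BAD


def make_gilbert_elliot(f: float, t: float, f_G: float = 0.0, f_B: float = 1.0) -> GilbertElliotSpec:
    """Parameterise a Gilbert-Elliott channel by mean error ``f`` and burstiness ``t``.

    ``p_b = 1/t``; ``p_g`` is solved from stationarity so the long-run mean
    flip rate equals ``f``: with occupancy ``pi_B = (f - f_G)/(f_B - f_G)``,
    ``p_g = p_b (1 - pi_B)/pi_B``.  For the default on/off states this is
    ``p_g = p_b (1 - f)/f``.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"mean error f must be in (0, 1), got {f}")
    if t <= 1.0:
        raise ValueError(f"burstiness t must exceed 1, got {t}")
    if f_B == f_G:
        raise ValueError("f_B must differ from f_G")
    pi_b = (f - f_G) / (f_B - f_G)
    if not 0.0 < pi_b < 1.0:
        raise ValueError("f must lie strictly between f_G and f_B")
    p_b = 1.0 / t
    p_g = p_b * (1.0 - pi_b) / pi_b
    if p_g > 1.0:
        t_min = (1.0 - pi_b) / pi_b
        raise ValueError(
            f"burstiness t={t} too small for mean error f={f}: leaving the bad "
            f"state would need probability {p_g:.3g} > 1; use t >= {t_min:.3g}")
    return GilbertElliotSpec(f=f, t=t, p_b=p_b, p_g=p_g, f_G=f_G, f_B=f_B)


def ge_step(state: ChannelState, spec: GilbertElliotSpec, intended_bit: int,
            rng: np.random.Generator) -> tuple[int, ChannelState]:
    """Advance the Markov chain one step and transmit one bit.

    The transition is drawn first and the flip probability of the
    post-transition state is applied (fixed convention).
    """
    if state.state == GOOD:
        new = BAD if rng.random() < spec.p_b else GOOD
    else:
        new = GOOD if rng.random() < spec.p_g else BAD
    f_flip = spec.f_B if new == BAD else spec.f_G
    flipped = rng.random() < f_flip
    observed = (1 - intended_bit) if flipped else intended_bit
    return observed, ChannelState(state=new)


# ---------------------------------------------------------------------------
# Stateful runtime wrappers used by the Monte Carlo simulator
# ---------------------------------------------------------------------------


class BernoulliChannel:
    """Runtime wrapper for a memoryless channel."""

    def __init__(self, spec: BinaryChannelSpec):
        self.spec = spec

    def reset(self, rng: np.random.Generator) -> None:  # noqa: ARG002 - stateless
        pass

    def send(self, bit: int, rng: np.random.Generator) -> int:
        return transmit(bit, self.spec, rng)


class GilbertElliotChannel:
    """Runtime wrapper holding the Markov state of a bursty channel.

    ``reset`` redraws the state from the stationary distribution so batches
    of trials see the long-run mean error rate.
    """

    def __init__(self, spec: GilbertElliotSpec):
        self.spec = spec
        self.state = ChannelState(GOOD)

    def reset(self, rng: np.random.Generator) -> None:
        self.state = ChannelState(BAD if rng.random() < self.spec.stationary_bad else GOOD)

    def send(self, bit: int, rng: np.random.Generator) -> int:
        observed, self.state = ge_step(self.state, self.spec, bit, rng)
        return observed


def channel_from_json(obj: Union[dict, str]):
    """Build a runtime channel from a JSON config block.

    ``{"f0": .., "f1": ..}`` gives a memoryless channel;
    ``{"model": "gilbert_elliot", "f": .., "t": ..}`` a bursty one.
    """
    if isinstance(obj, str):
        obj = json.loads(obj)
    if obj.get("model") == "gilbert_elliot":
        return GilbertElliotChannel(GilbertElliotSpec.from_json(obj))
    return BernoulliChannel(BinaryChannelSpec.from_json(obj))
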