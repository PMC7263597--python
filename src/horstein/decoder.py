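"""Posterior-matching (Horstein) feedback decoder over the unit interval.

The decoder maintains a belief about the user's intended target as a
monotone piecewise-linear CDF on [0, 1] (equivalently, a mixture-of-uniforms
density).  Each binary input splits the belief at its median and rescales
the two sides by the Bayes factors implied by the configured flip
probabilities; selection terminates once the differential entropy of the
belief has dropped by ``k + beta`` bits, at which point the symbol whose
interval contains the median is emitted.

With noise-free configuration this reduces exactly to bisection; with noise
it is the optimal feedback code for a memoryless binary channel with known
statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PiecewiseCDF",
    "DecoderConfig",
    "DecoderState",
    "init_decoder",
    "median",
    "quantile",
    "update",
    "update_weighted",
    "entropy",
    "accumulated_information",
    "is_terminated",
    "decode_symbol",
    "trisect_update",
    "qary_update",
    "undo",
]

_MERGE_TOL = 1e-12  # breakpoints closer than this are merged
_FMAX = 0.5 - 1e-6  # configured flip probabilities are capped below 1/2


@dataclass
class PiecewiseCDF:
    """Monotone piecewise-linear CDF on [0, 1].

    ``x`` holds ordered breakpoints with ``x[0] == 0`` and ``x[-1] == 1``;
    ``F`` the cumulative values at those breakpoints, ``F[0] == 0`` and
    ``F[-1] == 1``.  The density is constant on each segment.
    """

    x: np.ndarray
    F: np.ndarray

    @classmethod
    def uniform(cls) -> "PiecewiseCDF":
        return cls(np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    @classmethod
    def from_segment_masses(cls, masses: Sequence[float]) -> "PiecewiseCDF":
        """Equal-width segments carrying the given probability masses."""
        m = np.asarray(masses, dtype=float)
        if m.ndim != 1 or m.size == 0 or np.any(m <= 0.0):
            raise ValueError("masses must be a non-empty sequence of positive numbers")
        n = m.size
        x = np.linspace(0.0, 1.0, n + 1)
        F = np.concatenate([[0.0], np.cumsum(m / m.sum())])
        F[-1] = 1.0
        return cls(x, F)

    def copy(self) -> "PiecewiseCDF":
        return PiecewiseCDF(self.x.copy(), self.F.copy())

    # -- queries ----------------------------------------------------------

    def cdf(self, x: float) -> float:
        return float(np.interp(x, self.x, self.F))

    def quantile(self, q: float) -> float:
        """Inverse CDF by linear interpolation.

        A zero-density plateau exactly at level ``q`` (possible only with a
        noise-free configuration) returns the plateau midpoint.
        """
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"quantile level must be in [0, 1], got {q}")
        if q == 0.0:
            return 0.0
        if q == 1.0:
            return 1.0
        lo = int(np.searchsorted(self.F, q, side="left"))
        hi = int(np.searchsorted(self.F, q, side="right"))
        if hi - lo > 1:  # plateau: F == q on [x[lo], x[hi-1]]
            return 0.5 * (self.x[lo] + self.x[hi - 1])
        i = min(max(lo, 1), len(self.x) - 1)
        F0, F1 = self.F[i - 1], self.F[i]
        if F1 == F0:
            return 0.5 * (self.x[i - 1] + self.x[i])
        return float(self.x[i - 1] + (q - F0) * (self.x[i] - self.x[i - 1]) / (F1 - F0))

    def median(self) -> float:
        return self.quantile(0.5)

    def entropy_bits(self) -> float:
        """Differential entropy of the mixture-of-uniforms density, in bits.

        Segments with zero mass contribute nothing.
        """
        w = np.diff(self.x)
        m = np.diff(self.F)
        pos = m > 0.0
        if not np.any(pos):
            return 0.0
        return float(-np.sum(m[pos] * np.log2(m[pos] / w[pos])))

    def segment_masses(self) -> np.ndarray:
        return np.diff(self.F)

    def densities(self) -> np.ndarray:
        return np.diff(self.F) / np.diff(self.x)

    # -- mutation ---------------------------------------------------------

    def insert(self, xq: float) -> int:
        """Insert a breakpoint at ``xq`` (no-op if one is already there).

        Returns the index of the breakpoint.  Breakpoints closer than the
        merge tolerance to an existing one are not duplicated.
        """
        i = int(np.searchsorted(self.x, xq))
        if i > 0 and abs(self.x[i - 1] - xq) <= _MERGE_TOL:
            return i - 1
        if i < len(self.x) and abs(self.x[i] - xq) <= _MERGE_TOL:
            return i
        Fq = self.cdf(xq)
        # interpolation rounding must not break monotonicity by an ulp
        Fq = min(max(Fq, self.F[i - 1] if i > 0 else 0.0),
                 self.F[i] if i < len(self.F) else 1.0)
        self.x = np.insert(self.x, i, xq)
        self.F = np.insert(self.F, i, Fq)
        return i

    def scale_regions(self, boundaries: Sequence[float], factors: Sequence[float]) -> None:
        """Rescale the mass between consecutive boundaries by ``factors``.

        ``boundaries`` are interior split points (breakpoints are inserted as
        needed); ``factors`` has one entry per resulting region and must map
        the region masses to a new total of 1 (renormalised exactly).
        """
        idx = [0]
        for b in boundaries:
            idx.append(self.insert(b))
        idx.append(len(self.x) - 1)
        m = np.diff(self.F)
        for (a, b), g in zip(zip(idx[:-1], idx[1:]), factors):
            m[a:b] = m[a:b] * g
        total = m.sum()
        if total <= 0.0:
            raise ValueError("update annihilated all probability mass")
        # cumsum can overshoot 1 by an ulp before the endpoint is pinned
        F = np.minimum(np.concatenate([[0.0], np.cumsum(m / total)]), 1.0)
        F[-1] = 1.0
        self.F = F

    def to_json(self) -> dict:
        return {"x": self.x.tolist(), "F": self.F.tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> "PiecewiseCDF":
        return cls(np.asarray(obj["x"], dtype=float), np.asarray(obj["F"], dtype=float))


def _cap_flip(name: str, v: float) -> float:
    if not 0.0 <= v < 0.5:
        raise ValueError(f"{name} must be in [0, 0.5) (an input with flip rate >= 0.5 "
                         f"is uninformative or inverted), got {v}")
    return min(v, _FMAX)


@dataclass(frozen=True)
class DecoderConfig:
    """Configuration of a block Horstein decoder.

    ``k`` is the symbol length in bits (2**k targets), ``beta`` the
    confirmation overhead in bits (may be fractional), ``f0p``/``f1p`` the
    flip probabilities the decoder is configured for (typically the expected
    rates plus the headroom ``f_h``), and ``prior`` an optional non-uniform
    distribution over the targets (probability masses, summing to 1, placed
    on equal-width target intervals).
    """

    k: int
    beta: float = 0.0
    f0p: float = 0.0
    f1p: float = 0.0
    f_h: float = 0.0  # documentation field: f0p = f0_hat + f_h etc.
    prior: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        object.__setattr__(self, "f0p", _cap_flip("f0p", self.f0p))
        object.__setattr__(self, "f1p", _cap_flip("f1p", self.f1p))
        if self.prior is not None:
            pr = tuple(float(p) for p in self.prior)
            if any(p <= 0.0 for p in pr):
                raise ValueError("prior masses must be positive")
            s = sum(pr)
            if abs(s - 1.0) > 1e-9:
                pr = tuple(p / s for p in pr)
            object.__setattr__(self, "prior", pr)

    @property
    def n_targets(self) -> int:
        return len(self.prior) if self.prior is not None else 2 ** self.k

    def bayes_p(self, f0: float | None = None, f1: float | None = None) -> float:
        """Posterior mass left of the split after observing b=0."""
        f0 = self.f0p if f0 is None else f0
        f1 = self.f1p if f1 is None else f1
        return (1.0 - f0) / ((1.0 - f0) + f1)

    def bayes_q(self, f0: float | None = None, f1: float | None = None) -> float:
        """Posterior mass right of the split after observing b=1."""
        f0 = self.f0p if f0 is None else f0
        f1 = self.f1p if f1 is None else f1
        return (1.0 - f1) / ((1.0 - f1) + f0)


@dataclass
class DecoderState:
    """Belief state of one decoder: CDF, entropy bookkeeping and snapshots.

    ``snapshots`` holds one ``(entropy, cdf)`` pair per consumed input plus
    the prior, enabling information-metered undo.
    """

    config: DecoderConfig
    cdf: PiecewiseCDF
    inputs_consumed: int = 0
    entropy_bits: float = 0.0
    prior_entropy: float = 0.0
    snapshots: list[tuple[float, PiecewiseCDF]] = field(default_factory=list)

    def _snapshot(self) -> None:
        self.snapshots.append((self.entropy_bits, self.cdf.copy()))

    def to_json(self) -> dict:
        return {
            "config": {
                "k": self.config.k, "beta": self.config.beta,
                "f0p": self.config.f0p, "f1p": self.config.f1p,
                "f_h": self.config.f_h,
                "prior": list(self.config.prior) if self.config.prior else None,
            },
            "cdf": self.cdf.to_json(),
            "inputs_consumed": self.inputs_consumed,
            "entropy_bits": self.entropy_bits,
            "prior_entropy": self.prior_entropy,
            "snapshots": [{"entropy": h, "cdf": c.to_json()} for h, c in self.snapshots],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "DecoderState":
        cfg = obj["config"]
        config = DecoderConfig(k=cfg["k"], beta=cfg["beta"], f0p=cfg["f0p"],
                               f1p=cfg["f1p"], f_h=cfg.get("f_h", 0.0),
                               prior=tuple(cfg["prior"]) if cfg.get("prior") else None)
        state = cls(config=config, cdf=PiecewiseCDF.from_json(obj["cdf"]),
                    inputs_consumed=obj["inputs_consumed"],
                    entropy_bits=obj["entropy_bits"],
                    prior_entropy=obj["prior_entropy"],
                    snapshots=[(s["entropy"], PiecewiseCDF.from_json(s["cdf"]))
                               for s in obj["snapshots"]])
        return state


def init_decoder(config: DecoderConfig) -> DecoderState:
    """Fresh decoder: uniform belief, or the configured prior over targets.

    A non-uniform prior places each target's probability mass on its
    equal-width interval, so the initial entropy is the (negative) relative
    entropy of the prior versus uniform.
    """
    if config.prior is None:
        cdf = PiecewiseCDF.uniform()
    else:
        cdf = PiecewiseCDF.from_segment_masses(config.prior)
    h = cdf.entropy_bits()
    state = DecoderState(config=config, cdf=cdf, entropy_bits=h, prior_entropy=h)
    state._snapshot()
    return state


def median(state: DecoderState) -> float:
    return state.cdf.median()


def quantile(state: DecoderState, q: float) -> float:
    return state.cdf.quantile(q)


def entropy(state: DecoderState) -> float:
    """Differential entropy of the current belief, in bits."""
    return state.entropy_bits


def accumulated_information(state: DecoderState) -> float:
    """Entropy drop since the prior, H_0 - H_i, in bits."""
    return state.prior_entropy - state.entropy_bits


def is_terminated(state: DecoderState) -> bool:
    """True once the belief's entropy has dropped by at least k + beta bits."""
    return accumulated_information(state) >= state.config.k + state.config.beta


def _apply_median_split(state: DecoderState, left_mass: float) -> None:
    m = state.cdf.median()
    state.cdf.scale_regions([m], [left_mass / 0.5, (1.0 - left_mass) / 0.5])
    state.entropy_bits = state.cdf.entropy_bits()
    state.inputs_consumed += 1
    state._snapshot()


def update(state: DecoderState, b: int) -> DecoderState:
    """Consume one binary input: split at the median, reweight by Bayes.

    After observing ``b = 0`` the mass left of the old median becomes
    ``p = (1-f0')/((1-f0')+f1')``; after ``b = 1`` it becomes ``1-q`` with
    ``q = (1-f1')/((1-f1')+f0')``.  The state is modified in place and
    returned.
    """
    return update_weighted(state, b, state.config.f0p, state.config.f1p)


def update_weighted(state: DecoderState, b: int, f0_i: float, f1_i: float) -> DecoderState:
    """As :func:`update` but with per-decision flip probabilities.

    Used when the input device reports a per-decision reliability (e.g. a
    probabilistic classifier) instead of a fixed calibrated rate.
    """
    f0_i = _cap_flip("f0_i", f0_i)
    f1_i = _cap_flip("f1_i", f1_i)
    cfg = state.config
    if b == 0:
        left = cfg.bayes_p(f0_i, f1_i)
    elif b == 1:
        left = 1.0 - cfg.bayes_q(f0_i, f1_i)
    else:
        raise ValueError(f"input bit must be 0 or 1, got {b}")
    _apply_median_split(state, left)
    return state


def trisect_update(state: DecoderState, b: str) -> DecoderState:
    """Inner/outer input variant: split at the 25% and 75% quantiles.

    The central half of the mass plays the role of one side of a bisection
    (prior mass 0.5 each), so the same Bayes factors apply: ``b="inner"``
    scales the central region to mass ``p``, ``b="outer"`` to ``1-q``.
    """
    cfg = state.config
    if b == "inner":
        inner_mass = cfg.bayes_p()
    elif b == "outer":
        inner_mass = 1.0 - cfg.bayes_q()
    else:
        raise ValueError(f"trisection input must be 'inner' or 'outer', got {b!r}")
    q1 = state.cdf.quantile(0.25)
    q3 = state.cdf.quantile(0.75)
    outer_mass = 1.0 - inner_mass
    state.cdf.scale_regions([q1, q3],
                            [outer_mass / 0.5, inner_mass / 0.5, outer_mass / 0.5])
    state.entropy_bits = state.cdf.entropy_bits()
    state.inputs_consumed += 1
    state._snapshot()
    return state


def qary_update(state: DecoderState, symbol: int, q: int,
                f_b: float | Sequence[float]) -> DecoderState:
    """q-ary input: split at the q-1 quantiles and reweight by confusion.

    ``f_b`` is the per-symbol error probability (scalar, or one value per
    input symbol); an erroneous symbol is assumed equally likely to be any
    of the other q-1 symbols.  The segment matching the received symbol is
    scaled by its probability of correct reception, the others by their
    confusion likelihoods; with ``q=2`` this reduces exactly to
    :func:`update`.
    """
    if q < 2:
        raise ValueError(f"arity must be at least 2, got {q}")
    if not 0 <= symbol < q:
        raise ValueError(f"symbol {symbol} out of range for arity {q}")
    errs = np.full(q, float(f_b)) if np.isscalar(f_b) else np.asarray(f_b, dtype=float)
    if errs.shape != (q,):
        raise ValueError("f_b must be scalar or one error probability per symbol")
    if np.any(errs < 0.0) or np.any(errs > 1.0):
        raise ValueError("error probabilities must be in [0, 1]")
    # Likelihood of receiving `symbol` given the target lies in segment j:
    # the user sends j, received correctly w.p. 1-errs[j], confused to any
    # other symbol w.p. errs[j]/(q-1).
    lik = errs / (q - 1)
    lik[symbol] = 1.0 - errs[symbol]
    prior = np.full(q, 1.0 / q)
    post = prior * lik
    total = post.sum()
    if total <= 0.0:
        raise ValueError("received symbol has zero likelihood under every segment")
    post /= total
    bounds = [state.cdf.quantile(j / q) for j in range(1, q)]
    state.cdf.scale_regions(bounds, post / prior)
    state.entropy_bits = state.cdf.entropy_bits()
    state.inputs_consumed += 1
    state._snapshot()
    return state


def decode_symbol(state: DecoderState) -> int:
    """Symbol whose target interval contains the current median.

    Under the uniform layout this is ``floor(2^k * median)`` clamped to the
    top symbol; under a non-uniform prior, intervals are the equal-width
    cells of the prior's support.
    """
    n = state.config.n_targets
    m = state.cdf.median()
    return min(int(math.floor(n * m)), n - 1)


def undo(state: DecoderState, H_r: float) -> DecoderState:
    """Remove (as close as possible exactly) ``H_r`` bits of accumulated input.

    Restores the most recent snapshot whose accumulated information does not
    exceed the current accumulation minus ``H_r``; a fractional remainder is
    absorbed by partially reversing the following split, scaling its two
    sides toward equality until exactly ``H_r`` bits are removed (within
    1e-6).  ``H_r`` larger than everything accumulated resets to the prior.
    """
    if H_r < 0.0:
        raise ValueError(f"reversal information must be non-negative, got {H_r}")
    if H_r == 0.0:
        return state
    target = accumulated_information(state) - H_r
    if target <= 1e-12:
        _restore(state, 0)
        return state
    acc = [state.prior_entropy - h for h, _ in state.snapshots]
    j = max(i for i, a in enumerate(acc) if a <= target + 1e-12)
    if abs(acc[j] - target) <= 1e-9:
        _restore(state, j)
        return state
    # Partial reverse of the split j -> j+1: re-split snapshot j at its
    # median with a left mass between the original one and 1/2, chosen by
    # bisection so the accumulated information equals the target.
    base = state.snapshots[j][1]
    m = base.median()
    w_full = float(np.interp(m, state.snapshots[j + 1][1].x, state.snapshots[j + 1][1].F))

    def acc_at(w: float) -> tuple[float, PiecewiseCDF]:
        c = base.copy()
        c.scale_regions([m], [w / 0.5, (1.0 - w) / 0.5])
        return (state.prior_entropy - c.entropy_bits()), c

    lo, hi = 0.5, w_full  # lo gives accumulation acc[j] <= target
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        a, _ = acc_at(mid)
        if a < target:
            lo = mid
        else:
            hi = mid
        if abs(a - target) <= 1e-9:
            lo = hi = mid
            break
    a, partial = acc_at(0.5 * (lo + hi))
    _restore(state, j)
    state.cdf = partial
    state.entropy_bits = partial.entropy_bits()
    state.inputs_consumed = j + 1
    state.snapshots.append((state.entropy_bits, partial.copy()))
    return state


def _restore(state: DecoderState, j: int) -> None:
    h, cdf = state.snapshots[j]
    state.cdf = cdf.copy()
    state.entropy_bits = h
    state.inputs_consumed = j
    del state.snapshots[j + 1:]
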