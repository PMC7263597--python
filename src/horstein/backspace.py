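"""Backspace/undo reference code for noisy symbol entry.

A user enters a string of n symbols from a 2**k alphabet in which one symbol
is reserved as backspace.  Each symbol costs k binary decisions, each flipped
independently with probability f; a mis-entered symbol must be removed with
a backspace, which is itself a k-decision symbol subject to the same errors
(an erroneous backspace deletes a correct symbol, a mis-received backspace
commits junk).  This is the baseline that the feedback decoder is designed
to beat: above moderate error rates the correction cascade never terminates
and the effective capacity is zero.

The closed-form Gamma approximation of the entry rate and the concatenation
formula for backspace-correcting a residual symbol error rate live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "BackspaceResult",
    "simulate_backspace",
    "approx_backspace_rate",
    "backspace_corrected_rate",
    "delta_k",
]


def delta_k(k: int) -> float:
    """Alphabet-reservation overhead 2^k / (2^k - 1)."""
    return 2.0 ** k / (2.0 ** k - 1.0)


@dataclass(frozen=True)
class BackspaceResult:
    """Monte Carlo estimate of backspace-entry throughput."""

    k: int
    f: float
    n: int
    N: int
    rate_mean: float        # decisions per correct bit, over completed replicates
    rate_sd: float
    failed_fraction: float  # replicates that exhausted the step budget
    seed: int | None = None

    @property
    def failed(self) -> bool:
        return self.failed_fraction > 0.0

    def to_row(self) -> dict:
        return {"k": self.k, "f": self.f, "n": self.n, "N": self.N,
                "R_mean": self.rate_mean, "R_sd": self.rate_sd,
                "failed_fraction": self.failed_fraction, "seed": self.seed}


def simulate_backspace(k: int, f: float, n: int = 32, N: int = 1000,
                       rng: np.random.Generator | None = None,
                       budget_decisions: int | None = None,
                       seed: int | None = None) -> BackspaceResult:
    """Simulate perfect-strategy entry of ``n`` symbols over ``N`` replicates.

    The simulated user always knows the string state: they enter backspace
    iff the last committed symbol is wrong, and the next intended symbol
    otherwise.  Entry of one symbol draws k independent bit flips at rate
    ``f`` applied to the intended codeword; the backspace codeword is the
    all-ones pattern and targets are drawn uniformly from the remaining
    2^k - 1 symbols.  Replicates that exhaust the decision budget
    (default ``10**4 * n * k``) are flagged failed and excluded from the
    rate statistics (an unbounded correction cascade has infinite rate).
    """
    if k < 2:
        raise ValueError(f"k must be at least 2 (3 terminals + backspace), got {k}")
    if not 0.0 <= f < 0.5:
        raise ValueError(f"flip probability must be in [0, 0.5), got {f}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if budget_decisions is None:
        budget_decisions = 10_000 * n * k
    max_attempts = budget_decisions // k

    nsym = 2 ** k
    backspace = nsym - 1
    good = np.zeros(N, dtype=np.int64)    # length of correct committed prefix
    bad = np.zeros(N, dtype=np.int64)     # wrong symbols stacked on top
    attempts = np.zeros(N, dtype=np.int64)
    active = np.ones(N, dtype=bool)
    # Intended target sequences, drawn uniformly from non-backspace symbols.
    targets = rng.integers(0, nsym - 1, size=(N, n))

    for _ in range(max_attempts):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        intend_bs = bad[idx] > 0
        intended = np.where(intend_bs, backspace,
                            targets[idx, np.minimum(good[idx], n - 1)])
        if f > 0.0:
            flips = rng.random((idx.size, k)) < f
            mask = (flips * (1 << np.arange(k))).sum(axis=1).astype(np.int64)
        else:
            mask = np.zeros(idx.size, dtype=np.int64)
        received = intended ^ mask
        attempts[idx] += 1

        is_bs = received == backspace
        ok = received == intended
        # intending a target symbol:
        tgt = ~intend_bs
        good[idx[tgt & ok]] += 1
        del_ok = tgt & is_bs & ~ok          # spurious backspace deletes a good symbol
        good[idx[del_ok]] = np.maximum(good[idx[del_ok]] - 1, 0)
        bad[idx[tgt & ~ok & ~is_bs]] += 1   # committed a wrong symbol
        # intending backspace:
        bad[idx[intend_bs & is_bs]] -= 1    # removed the offending symbol
        bad[idx[intend_bs & ~is_bs]] += 1   # committed more junk instead
        active[idx] = ~((good[idx] >= n) & (bad[idx] == 0))

    failed = active
    completed = ~failed
    # Decisions per correct bit: k decisions per attempt over n*k committed
    # bits, times the reservation overhead delta_k (one codeword of the 2^k
    # carries no payload).  At f=0 this is exactly delta_k.
    rates = delta_k(k) * attempts[completed] / n
    if completed.any():
        mean = float(rates.mean())
        sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    else:
        mean, sd = float("inf"), float("nan")
    return BackspaceResult(k=k, f=f, n=n, N=N, rate_mean=mean, rate_sd=sd,
                           failed_fraction=float(failed.mean()), seed=seed)


def approx_backspace_rate(k: int, f: float) -> float:
    """Closed-form Gamma approximation of the backspace entry rate.

    ``delta_k * (Gamma(2*p_k - 1) + 1 - p_k)`` with ``p_k = (1-f)**k``.
    Outside the regime where backspace functions (``2*p_k - 1 <= 0``, or a
    negative value of the expression) the rate is infinite.
    """
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if not 0.0 <= f < 1.0:
        raise ValueError(f"flip probability must be in [0, 1), got {f}")
    p_k = (1.0 - f) ** k
    arg = 2.0 * p_k - 1.0
    if arg <= 0.0:
        return float("inf")
    r = delta_k(k) * (float(_gamma(arg)) + 1.0 - p_k)
    return r if r > 0.0 else float("inf")


def backspace_corrected_rate(R: float, e_k: float, k: int) -> float:
    """Decisions per error-free bit after concatenating a backspace code.

    ``R' = R * delta_k * (Gamma(2*(1-e_k) - 1) + e_k)``; infinite once the
    residual symbol error rate ``e_k`` reaches 1/2 (correction cascade).
    """
    if not 0.0 <= e_k < 1.0:
        raise ValueError(f"residual symbol error must be in [0, 1), got {e_k}")
    arg = 2.0 * (1.0 - e_k) - 1.0
    if arg <= 0.0:
        return float("inf")
    r = R * delta_k(k) * (float(_gamma(arg)) + e_k)
    return r if r > 0.0 else float("inf")
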