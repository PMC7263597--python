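"""Online adaptation of the decoder's configured channel statistics.

Channel error rates drift in real use (electrode drying, fatigue, lighting),
so the decoder's configured flip probabilities can be nudged between symbols
to track the truth without an explicit calibration procedure.

Two rules are provided.  The symmetric rule compares the number of inputs a
symbol actually took against the count expected from the configured
capacity and steps f' up or down outside a dead-band.  The biased rule
replays the just-finished selection in simulation with the configured
probabilities as the simulated noise, and moves f0'/f1' toward the truth in
proportion to the mismatch in received 0/1 counts.  Both rules apply only
between symbols, never mid-symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import decoder as hd
from .channels import capacity_bac

__all__ = ["AdaptationState", "adapt_symmetric", "adapt_biased"]

_F_LO, _F_HI = 0.0, 0.499


@dataclass
class AdaptationState:
    """Configured flip probabilities plus the tuning constants of both rules.

    ``eps_n`` is the dead-band (symmetric rule) or learning rate (biased
    rule); ``delta_n`` the fixed step of the symmetric rule.  Defaults are
    the values used for the convergence simulations: symmetric
    ``eps_n=0.01``, ``delta_n=0.005``; the biased rule wants a much smaller
    ``eps_n`` (0.0005).
    """

    f0p: float
    f1p: float
    eps_n: float = 0.01
    delta_n: float = 0.005

    def clamped(self, f0p: float, f1p: float) -> "AdaptationState":
        return replace(self,
                       f0p=float(np.clip(f0p, _F_LO, _F_HI)),
                       f1p=float(np.clip(f1p, _F_LO, _F_HI)))


def expected_inputs_per_symbol(state: AdaptationState, config: hd.DecoderConfig) -> float:
    """Expected inputs to drop k + beta bits at the configured capacity."""
    c = capacity_bac(state.f0p, state.f1p)
    c = max(c, 1e-9)
    return (config.k + config.beta) / c

def adapt_symmetric(state: AdaptationState, n: int,
                    config: hd.DecoderConfig) -> AdaptationState:
    """Count-based rule for symmetric channels, applied after each symbol.

    With ``n_p`` the expected per-symbol input count, the relative deviation
    ``(n - n_p)/n_p`` is compared against the dead-band ``eps_n``: too many
    inputs means the channel is worse than configured (step f' up by
    ``delta_n``), too few means it is better (step down), otherwise leave
    unchanged.  Both configured probabilities move together.
    """
    n_p = expected_inputs_per_symbol(state, config)
    rel = (n - n_p) / n_p
    if rel > state.eps_n:
        step = state.delta_n
    elif rel < -state.eps_n:
        step = -state.delta_n
    else:
        step = 0.0
    return state.clamped(state.f0p + step, state.f1p + step)


def adapt_biased(state: AdaptationState, n0: int, n1: int, target_symbol: int,
                 config: hd.DecoderConfig, rng: np.random.Generator,
                 replicates: int = 4) -> AdaptationState:
    """Replicate-simulation rule for biased channels.

    The selection of ``target_symbol`` is re-run ``replicates`` times with
    the *configured* probabilities as the simulated noise level; the mean
    received-bit counts (n0', n1') of those replicates are compared with the
    observed counts and the configured probabilities nudged:
    ``f0' += eps_n (n0 - n0')/k`` and likewise for f1'.  At the truth this
    is an unbiased fixed point.
    """
    from .channels import BinaryChannelSpec, BernoulliChannel
    from .montecarlo import OracleUser, run_selection, symbol_centre

    if replicates < 1:
        raise ValueError(f"need at least one replicate, got {replicates}")
    cfg = hd.DecoderConfig(k=config.k, beta=config.beta,
                           f0p=state.f0p, f1p=state.f1p, prior=config.prior)
    sim_channel = BernoulliChannel(BinaryChannelSpec(f0=state.f0p, f1=state.f1p))
    theta = symbol_centre(target_symbol, config.k)
    n0s, n1s = [], []
    for _ in range(replicates):
        rec = run_selection(cfg, sim_channel, OracleUser(theta=theta), rng)
        n0s.append(rec.n0)
        n1s.append(rec.n1)
    n0p = float(np.mean(n0s))
    n1p = float(np.mean(n1s))
    k = config.k
    return state.clamped(state.f0p + state.eps_n * (n0 - n0p) / k,
                         state.f1p + state.eps_n * (n1 - n1p) / k)
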