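"""Offline Monte Carlo simulator for the feedback decoder.

An oracle user with a fixed intended target answers every median query
perfectly; the answers pass through a noisy channel before reaching the
decoder.  Batches of simulated selections estimate the decisions-per-bit
rate R, the uncorrected symbol error rate e_k, and the backspace-corrected
rate R' that a concatenated undo code would achieve — the quantities needed
to evaluate an interface design before any human trial.

Also provided: bisection of the confirmation overhead beta to hit a target
error rate, a closed-form log-linear error predictor fitted to simulation,
change-of-heart experiments (the user switches target mid-selection), and
a diffused-decoder batch mode that interleaves independent decoders to
decorrelate bursty noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import decoder as hd
from .backspace import backspace_corrected_rate
from .channels import capacity_bac

__all__ = [
    "OracleUser",
    "TrialRecord",
    "SimulationResult",
    "run_selection",
    "run_batch",
    "run_diffused_batch",
    "bisect_beta",
    "predict_error_rate",
    "evaluate_scenario",
    "symbol_centre",
    "default_input_budget",
]


def symbol_centre(symbol: int, k: int) -> float:
    """Centre of a symbol's target interval under the uniform 2^k layout."""
    return (symbol + 0.5) / 2 ** k


@dataclass
class OracleUser:
    """Simulated user who always answers median queries perfectly.

    ``theta`` is the centre of the intended symbol's interval.  An optional
    change-of-heart is triggered the first time the decoder's entropy drops
    below ``-lam * (k + beta)``: the target switches to the symbol centre at
    distance ``x_delta`` (kept inside [0, 1]; ties resolved rightward).
    ``extra_error_rate`` adds human slips on top of the channel noise.
    """

    theta: float
    lam: float | None = None
    x_delta: float = 0.0
    extra_error_rate: float = 0.0
    switched: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"target must lie in [0, 1], got {self.theta}")
        if self.lam is not None and not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"switchpoint fraction must be in [0, 1], got {self.lam}")
        if not 0.0 <= self.x_delta <= 1.0:
            raise ValueError(f"target separation must be in [0, 1], got {self.x_delta}")

    def maybe_switch(self, state: hd.DecoderState) -> None:
        if self.lam is None or self.switched:
            return
        h_threshold = -self.lam * (state.config.k + state.config.beta)
        if hd.entropy(state) < h_threshold:
            right = self.theta + self.x_delta
            new = right if right <= 1.0 else self.theta - self.x_delta
            k = state.config.k
            s = min(max(int(math.floor(new * 2 ** k)), 0), 2 ** k - 1)
            self.theta = symbol_centre(s, k)
            self.switched = True

    def answer(self, median: float, rng: np.random.Generator) -> int:
        b = 0 if self.theta < median else 1
        if self.extra_error_rate > 0.0 and rng.random() < self.extra_error_rate:
            b = 1 - b
        return b


@dataclass
class TrialRecord:
    """Outcome of one simulated selection."""

    inputs: int
    decoded: int
    correct: bool
    n0: int                      # received zeros (used by biased adaptation)
    n1: int                      # received ones
    aborted: bool = False
    intended_bits: list[int] | None = None
    observed_bits: list[int] | None = None


@dataclass
class SimulationResult:
    """Aggregate metrics of a batch of simulated selections."""

    N: int
    k: int
    beta: float
    R_mean: float          # input decisions per decoded bit
    R_sd: float            # sd of per-trial decisions/bit
    e_k: float             # fraction of symbols decoded incorrectly
    R_prime: float         # backspace-corrected decisions per error-free bit
    seed: int | None = None

    def time_per_symbol(self, t_i: float) -> float:
        """Projected seconds per decoded symbol at t_i seconds per decision."""
        return self.R_mean * self.k * t_i

    def time_per_correct_symbol(self, t_i: float) -> float:
        """Projected seconds per error-free symbol via backspace correction."""
        return self.R_prime * self.k * t_i


def default_input_budget(config: hd.DecoderConfig) -> int:
    """Abort threshold for pathological selections."""
    c = capacity_bac(config.f0p, config.f1p)
    c = max(c, 1e-3)
    return int(math.ceil(50.0 * (config.k + config.beta) / c))


def run_selection(config: hd.DecoderConfig, channel, user: OracleUser,
                  rng: np.random.Generator, input_budget: int | None = None,
                  record_bits: bool = False) -> TrialRecord:
    """Run one complete selection and record its outcome.

    The loop follows the decoder's protocol: show the median, let the oracle
    answer, corrupt the answer in the channel, update, until the entropy
    drop reaches k + beta.  A trial that exhausts the input budget is
    aborted and flagged incorrect.
    """
    if input_budget is None:
        input_budget = default_input_budget(config)
    state = hd.init_decoder(config)
    channel.reset(rng)
    n0 = n1 = 0
    intended: list[int] | None = [] if record_bits else None
    observed: list[int] | None = [] if record_bits else None
    aborted = False
    while not hd.is_terminated(state):
        if state.inputs_consumed >= input_budget:
            aborted = True
            break
        m = hd.median(state)
        b_intent = user.answer(m, rng)
        b = channel.send(b_intent, rng)
        if record_bits:
            intended.append(b_intent)
            observed.append(b)
        if b == 0:
            n0 += 1
        else:
            n1 += 1
        hd.update(state, b)
        user.maybe_switch(state)
    decoded = hd.decode_symbol(state)
    n = config.n_targets
    cell = int(math.floor(user.theta * n))
    correct = (not aborted) and decoded == min(cell, n - 1)
    return TrialRecord(inputs=state.inputs_consumed, decoded=decoded,
                       correct=correct, n0=n0, n1=n1, aborted=aborted,
                       intended_bits=intended, observed_bits=observed)


def _draw_target(config: hd.DecoderConfig, rng: np.random.Generator) -> float:
    n = config.n_targets
    if config.prior is None:
        s = int(rng.integers(n))
    else:
        s = int(rng.choice(n, p=np.asarray(config.prior)))
    return (s + 0.5) / n


def _aggregate(records: Sequence[TrialRecord], config: hd.DecoderConfig,
               seed: int | None) -> SimulationResult:
    k = config.k
    inputs = np.array([r.inputs for r in records], dtype=float)
    per_trial = inputs / k
    R = float(inputs.sum() / (len(records) * k))
    e_k = float(np.mean([not r.correct for r in records]))
    return SimulationResult(
        N=len(records), k=k, beta=config.beta,
        R_mean=R,
        R_sd=float(per_trial.std(ddof=1)) if len(records) > 1 else 0.0,
        e_k=e_k,
        R_prime=backspace_corrected_rate(R, e_k, k),
        seed=seed,
    )


def run_batch(config: hd.DecoderConfig, channel, N: int,
              rng: np.random.Generator | None = None, seed: int | None = None,
              user_kwargs: dict | None = None,
              input_budget: int | None = None) -> SimulationResult:
    """Run ``N`` independent selections of random targets and aggregate.

    Targets are drawn uniformly from the symbol centres (or from the
    configured prior).  R counts the inputs of incorrect trials too; e_k is
    reported separately.
    """
    if N < 1:
        raise ValueError(f"N must be positive, got {N}")
    if rng is None:
        rng = np.random.default_rng(seed)
    records = []
    for _ in range(N):
        user = OracleUser(theta=_draw_target(config, rng), **(user_kwargs or {}))
        records.append(run_selection(config, channel, user, rng,
                                     input_budget=input_budget))
    return _aggregate(records, config, seed)


def run_diffused_batch(config: hd.DecoderConfig, channel, n_decoders: int,
                       N_rounds: int, rng: np.random.Generator | None = None,
                       seed: int | None = None) -> SimulationResult:
    """Interleave independent decoders with uniformly random scheduling.

    In each round ``n_decoders`` decoders with independent targets share one
    channel; at every step a uniformly random unterminated decoder receives
    the next input.  Bursts of channel errors are thereby diffused across
    decoders.  Correctness is scored per decoder.
    """
    if n_decoders < 1:
        raise ValueError(f"need at least one decoder, got {n_decoders}")
    if rng is None:
        rng = np.random.default_rng(seed)
    budget = default_input_budget(config) * n_decoders
    records = []
    for _ in range(N_rounds):
        states = [hd.init_decoder(config) for _ in range(n_decoders)]
        users = [OracleUser(theta=_draw_target(config, rng)) for _ in range(n_decoders)]
        counts = [[0, 0] for _ in range(n_decoders)]
        channel.reset(rng)
        total = 0
        while True:
            open_idx = [i for i, s in enumerate(states) if not hd.is_terminated(s)]
            if not open_idx or total >= budget:
                break
            i = int(rng.choice(open_idx))
            b = channel.send(users[i].answer(hd.median(states[i]), rng), rng)
            counts[i][b] += 1
            hd.update(states[i], b)
            total += 1
        aborted = bool(open_idx)
        for i, s in enumerate(states):
            decoded = hd.decode_symbol(s)
            cell = min(int(math.floor(users[i].theta * config.n_targets)),
                       config.n_targets - 1)
            records.append(TrialRecord(
                inputs=s.inputs_consumed, decoded=decoded,
                correct=(not aborted) and decoded == cell,
                n0=counts[i][0], n1=counts[i][1], aborted=aborted))
    return _aggregate(records, config, seed)


def bisect_beta(k: int, f0p: float, f1p: float, channel, e_target: float,
                N: int, rng: np.random.Generator | None = None,
                seed: int | None = None, beta_max: float = 16.0,
                tol: float = 0.05, prior: tuple[float, ...] | None = None
                ) -> tuple[float, bool]:
    """Smallest beta (within ``tol`` bits) whose batch error meets ``e_target``.

    Monotone bisection on beta in [0, beta_max]; each evaluation is a fresh
    batch of N selections.  Returns ``(beta, ok)``; ``ok`` is False when
    even ``beta_max`` cannot reach the target error rate.
    """
    if rng is None:
        rng = np.random.default_rng(seed)

    def e_at(beta: float) -> float:
        cfg = hd.DecoderConfig(k=k, beta=beta, f0p=f0p, f1p=f1p, prior=prior)
        return run_batch(cfg, channel, N, rng).e_k

    if e_at(0.0) <= e_target:
        return 0.0, True
    if e_at(beta_max) > e_target:
        return beta_max, False
    lo, hi = 0.0, beta_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if e_at(mid) <= e_target:
            hi = mid
        else:
            lo = mid
    return hi, True


def predict_error_rate(f: float, beta: float) -> float:
    """Log-linear closed-form fit of the uncorrected symbol error rate.

    ``e_k(f) = exp(-0.28 (beta + 5.17)) f + exp(-1.19 (beta + 2.57))``:
    a line in f whose gradient and offset decay exponentially with beta,
    independent of k.
    """
    if not 0.0 <= f <= 0.5:
        raise ValueError(f"flip probability must be in [0, 0.5], got {f}")
    if beta < 0.0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    return math.exp(-0.28 * (beta + 5.17)) * f + math.exp(-1.19 * (beta + 2.57))


def evaluate_scenario(spec: dict, rng: np.random.Generator | None = None,
                      seed: int | None = None) -> dict:
    """Evaluate a design scenario and report its performance metrics.

    ``spec`` fields: ``k``; ``beta`` or ``e_target`` (the latter bisected);
    ``channel`` as ``{"f0":..,"f1":..}`` or ``{"model":"gilbert_elliot",..}``;
    ``configured`` as ``{"f0p":..,"f1p":..}``; optional ``t_i`` seconds per
    decision; optional ``N`` (default 2000).
    """
    from .channels import channel_from_json

    if rng is None:
        rng = np.random.default_rng(seed)
    k = int(spec["k"])
    channel = channel_from_json(spec["channel"])
    f0p = float(spec["configured"]["f0p"])
    f1p = float(spec["configured"]["f1p"])
    N = int(spec.get("N", 2000))
    bisected = False
    if "beta" in spec:
        beta = float(spec["beta"])
    elif "e_target" in spec:
        beta, ok = bisect_beta(k, f0p, f1p, channel, float(spec["e_target"]),
                               N=max(N // 2, 200), rng=rng)
        bisected = True
        if not ok:
            raise ValueError(f"target error rate {spec['e_target']} unreachable "
                             f"at beta <= 16")
    else:
        raise ValueError("scenario needs either 'beta' or 'e_target'")
    cfg = hd.DecoderConfig(k=k, beta=beta, f0p=f0p, f1p=f1p)
    res = run_batch(cfg, channel, N, rng, seed=seed)
    out = {"k": k, "beta": beta, "beta_bisected": bisected,
           "R": res.R_mean, "R_sd": res.R_sd, "e_k": res.e_k,
           "R_prime": res.R_prime, "N": N}
    if "t_i" in spec:
        t_i = float(spec["t_i"])
        out["T_k"] = res.time_per_symbol(t_i)
        out["T_k_corrected"] = res.time_per_correct_symbol(t_i)
    return out
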