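"""Belief maintenance: Bayesian median splits, entropy, termination, undo.

The independent oracle here is a brute-force Bayes computation on a
4096-bin discretised grid: bin masses are reweighted exactly (straddled
bins fractionally) at the same split points the decoder uses, so any
error in the decoder's piecewise-CDF arithmetic shows up as a per-bin
mass discrepancy.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import horstein as H

GRID = 4096


class GridOracle:
    """Exact Bayes updates of bin masses on a uniform grid."""

    def __init__(self, n=GRID):
        self.edges = np.linspace(0.0, 1.0, n + 1)
        self.mass = np.full(n, 1.0 / n)

    def update(self, split: float, left_mass: float):
        lo = self.edges[:-1]
        hi = self.edges[1:]
        frac_left = np.clip((split - lo) / (hi - lo), 0.0, 1.0)
        gl, gr = left_mass / 0.5, (1.0 - left_mass) / 0.5
        self.mass = self.mass * (frac_left * gl + (1.0 - frac_left) * gr)
        self.mass /= self.mass.sum()

    def bin_masses_of(self, state):
        F = np.interp(self.edges, state.cdf.x, state.cdf.F)
        return np.diff(F)


def left_mass_of(state):
    """Posterior mass left of 1/2 — for single-update checks on uniform priors."""
    return float(np.interp(0.5, state.cdf.x, state.cdf.F))


class TestInit:
    def test_uniform_prior(self, make_decoder):
        s = make_decoder()
        assert H.median(s) == pytest.approx(0.5)
        assert H.entropy(s) == 0.0
        assert not H.is_terminated(s)

    def test_balanced_prior_equals_uniform(self, make_decoder):
        s = make_decoder(prior=(0.5, 0.5))
        assert H.entropy(s) == pytest.approx(0.0, abs=1e-12)
        assert H.median(s) == pytest.approx(0.5)

    def test_skewed_prior_entropy(self, make_decoder):
        # two equal-width halves holding masses 0.75/0.25
        s = make_decoder(prior=(0.75, 0.25))
        expected = -(0.75 * math.log2(1.5) + 0.25 * math.log2(0.5))
        assert H.entropy(s) == pytest.approx(expected, abs=1e-12)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            H.DecoderConfig(k=2, prior=(0.5, -0.5, 1.0))

    def test_configured_rate_at_half_rejected(self):
        with pytest.raises(ValueError):
            H.DecoderConfig(k=2, f0p=0.5, f1p=0.1)


class TestUpdate:
    def test_noise_free_bisection_step(self, make_decoder):
        s = make_decoder(f0p=0.0, f1p=0.0)
        H.update(s, 0)
        assert left_mass_of(s) == pytest.approx(1.0, abs=1e-12)
        assert H.entropy(s) == pytest.approx(-1.0, abs=1e-12)
        assert H.median(s) == pytest.approx(0.25)

    def test_symmetric_noisy_step(self, make_decoder):
        s = make_decoder(f0p=0.1, f1p=0.1)
        H.update(s, 0)
        assert left_mass_of(s) == pytest.approx(0.9, abs=1e-12)
        expected_h = -(0.9 * math.log2(1.8) + 0.1 * math.log2(0.2))
        assert H.entropy(s) == pytest.approx(expected_h, abs=1e-12)
        assert H.median(s) == pytest.approx(0.5 / 1.8, abs=1e-12)

    def test_biased_step(self, make_decoder):
        s = make_decoder(f0p=0.05, f1p=0.45)
        H.update(s, 0)
        assert left_mass_of(s) == pytest.approx(0.95 / (0.95 + 0.45), abs=1e-12)

    def test_invalid_bit_rejected(self, make_decoder):
        with pytest.raises(ValueError):
            H.update(make_decoder(), 2)

    @given(bits=st.lists(st.integers(0, 1), min_size=1, max_size=40),
           f0p=st.floats(0.0, 0.45), f1p=st.floats(0.0, 0.45))
    @settings(max_examples=60, deadline=None)
    def test_mass_conserved_and_monotone(self, bits, f0p, f1p):
        s = H.init_decoder(H.DecoderConfig(k=4, f0p=f0p, f1p=f1p))
        for b in bits:
            H.update(s, b)
        assert abs(s.cdf.F[-1] - 1.0) < 1e-9
        assert np.all(np.diff(s.cdf.F) >= -1e-15)
        assert np.all(np.diff(s.cdf.x) > 0)

    @given(bits=st.lists(st.integers(0, 1), min_size=1, max_size=15))
    @settings(max_examples=40, deadline=None)
    def test_bayes_left_mass_each_step(self, bits):
        """Left-of-split posterior mass equals the Bayes factor exactly."""
        cfg = H.DecoderConfig(k=4, f0p=0.12, f1p=0.31)
        p, q = cfg.bayes_p(), cfg.bayes_q()
        s = H.init_decoder(cfg)
        for b in bits:
            m = H.median(s)
            H.update(s, b)
            got = float(np.interp(m, s.cdf.x, s.cdf.F))
            want = p if b == 0 else 1.0 - q
            assert got == pytest.approx(want, abs=1e-9)

    @given(bits=st.lists(st.integers(0, 1), min_size=1, max_size=20))
    @settings(max_examples=30, deadline=None)
    def test_mirror_equivariance(self, bits):
        """Relabelling 0<->1 and mirroring x -> 1-x with swapped f' matches."""
        a = H.init_decoder(H.DecoderConfig(k=4, f0p=0.1, f1p=0.3))
        b_ = H.init_decoder(H.DecoderConfig(k=4, f0p=0.3, f1p=0.1))
        for bit in bits:
            H.update(a, bit)
            H.update(b_, 1 - bit)
        np.testing.assert_allclose(a.cdf.x, 1.0 - b_.cdf.x[::-1], atol=1e-12)
        np.testing.assert_allclose(np.diff(a.cdf.F),
                                   np.diff(b_.cdf.F)[::-1], atol=1e-12)

    @given(bits=st.lists(st.integers(0, 1), min_size=1, max_size=3),
           f0p=st.floats(0.01, 0.45), f1p=st.floats(0.01, 0.45))
    @settings(max_examples=60, deadline=None)
    def test_posterior_matches_grid_oracle(self, bits, f0p, f1p):
        cfg = H.DecoderConfig(k=4, f0p=f0p, f1p=f1p)
        s = H.init_decoder(cfg)
        oracle = GridOracle()
        for b in bits:
            m = H.median(s)
            H.update(s, b)
            oracle.update(m, cfg.bayes_p() if b == 0 else 1.0 - cfg.bayes_q())
        np.testing.assert_allclose(oracle.bin_masses_of(s), oracle.mass, atol=1e-6)


class TestWeightedUpdate:
    def test_matches_plain_update_when_equal(self, make_decoder):
        a = make_decoder(f0p=0.2, f1p=0.2)
        b = make_decoder(f0p=0.2, f1p=0.2)
        for bit in [0, 1, 1, 0]:
            H.update(a, bit)
            H.update_weighted(b, bit, 0.2, 0.2)
        np.testing.assert_allclose(a.cdf.F, b.cdf.F, atol=1e-15)

    def test_uninformative_input_leaves_masses(self, make_decoder):
        s = make_decoder()
        H.update_weighted(s, 0, 0.499999, 0.499999)
        assert left_mass_of(s) == pytest.approx(0.5, abs=1e-5)
        assert s.inputs_consumed == 1
        assert len(s.snapshots) == 2

    def test_alternating_weighted_sequence_vs_hand_bayes(self, make_decoder):
        """Step-by-step hand evaluation of the posterior split masses."""
        s = make_decoder()
        expected_left = []
        for i, bit in enumerate([0, 1, 0, 1]):
            f0i, f1i = (0.1, 0.3) if i % 2 == 0 else (0.3, 0.1)
            m = H.median(s)
            H.update_weighted(s, bit, f0i, f1i)
            p = (1 - f0i) / ((1 - f0i) + f1i)
            q = (1 - f1i) / ((1 - f1i) + f0i)
            want = p if bit == 0 else 1 - q
            got = float(np.interp(m, s.cdf.x, s.cdf.F))
            assert got == pytest.approx(want, abs=1e-12)
            expected_left.append(want)
        assert len(expected_left) == s.inputs_consumed


class TestEntropyTermination:
    def test_three_noise_free_updates(self, make_decoder):
        s = make_decoder(f0p=0.0, f1p=0.0)
        for b in [0, 1, 0]:
            H.update(s, b)
        assert H.entropy(s) == pytest.approx(-3.0, abs=1e-12)

    def test_entropy_recomputable_from_cdf(self, make_decoder, rng):
        s = make_decoder(f0p=0.15, f1p=0.3)
        for _ in range(25):
            H.update(s, int(rng.integers(2)))
        assert H.entropy(s) == pytest.approx(s.cdf.entropy_bits(), abs=1e-9)

    @pytest.mark.parametrize("beta,n_inputs,done", [
        (0.0, 0, False), (0.0, 6, True), (0.5, 6, False), (0.5, 7, True),
    ])
    def test_termination_with_fractional_beta(self, beta, n_inputs, done):
        s = H.init_decoder(H.DecoderConfig(k=6, beta=beta, f0p=0.0, f1p=0.0))
        for _ in range(n_inputs):
            H.update(s, 0)
        assert H.is_terminated(s) is done

    @given(k=st.integers(2, 8), beta=st.floats(0.0, 3.0),
           target=st.integers(0, 255))
    @settings(max_examples=40, deadline=None)
    def test_noise_free_bisection_limit(self, k, beta, target):
        """Error-free selection takes exactly k + ceil(beta) inputs."""
        beta = round(beta, 2)  # avoid denormal betas below float resolution of k+beta
        target = target % 2 ** k
        theta = (target + 0.5) / 2 ** k
        s = H.init_decoder(H.DecoderConfig(k=k, beta=beta, f0p=0.0, f1p=0.0))
        n = 0
        while not H.is_terminated(s):
            H.update(s, 0 if theta < H.median(s) else 1)
            n += 1
        assert n == k + math.ceil(beta)
        assert H.decode_symbol(s) == target


class TestMedianQuantile:
    def test_quantile_extremes(self, uniform_state):
        assert H.quantile(uniform_state, 0.0) == 0.0
        assert H.quantile(uniform_state, 1.0) == 1.0

    def test_plateau_median_is_midpoint(self, make_decoder):
        # noise-free update puts zero density on [0.5, 1]; the 1.0-quantile
        # region is a plateau but interior quantiles stay in the mass
        s = make_decoder(f0p=0.0, f1p=0.0)
        H.update(s, 0)   # all mass on [0, 0.5]
        H.update(s, 1)   # all mass on [0.25, 0.5]
        assert H.median(s) == pytest.approx(0.375)
        # quantile inside the support
        assert H.quantile(s, 0.5) == pytest.approx(0.375)


class TestDecodeSymbol:
    def test_reference_decode(self, make_decoder):
        s = make_decoder(k=8, f0p=0.0, f1p=0.0)
        theta = 0.71875
        for _ in range(8):
            H.update(s, 0 if theta < H.median(s) else 1)
        assert H.decode_symbol(s) == 184  # floor(256 * 0.71875)

    def test_boundary_clamp(self):
        s = H.init_decoder(H.DecoderConfig(k=4, f0p=0.0, f1p=0.0))
        for _ in range(6):
            H.update(s, 1)  # drive median to 1.0
        assert H.decode_symbol(s) == 15

    def test_zero_median(self):
        s = H.init_decoder(H.DecoderConfig(k=4, f0p=0.0, f1p=0.0))
        for _ in range(6):
            H.update(s, 0)
        assert H.decode_symbol(s) == 0


class TestTrisect:
    def test_noise_free_inner(self, make_decoder):
        s = make_decoder(f0p=0.0, f1p=0.0)
        H.trisect_update(s, "inner")
        assert H.entropy(s) == pytest.approx(-1.0, abs=1e-12)
        # mass concentrated on the central half
        assert np.interp(0.25, s.cdf.x, s.cdf.F) == pytest.approx(0.0, abs=1e-12)
        assert np.interp(0.75, s.cdf.x, s.cdf.F) == pytest.approx(1.0, abs=1e-12)

    def test_uninformative(self, make_decoder):
        s = make_decoder(f0p=0.499999, f1p=0.499999)
        H.trisect_update(s, "inner")
        inner = np.interp(0.75, s.cdf.x, s.cdf.F) - np.interp(0.25, s.cdf.x, s.cdf.F)
        assert inner == pytest.approx(0.5, abs=1e-5)

    def test_inner_mass_is_bayes_p(self, make_decoder):
        s = make_decoder(f0p=0.1, f1p=0.1)
        H.trisect_update(s, "inner")
        inner = np.interp(0.75, s.cdf.x, s.cdf.F) - np.interp(0.25, s.cdf.x, s.cdf.F)
        assert inner == pytest.approx(0.9, abs=1e-12)

    def test_outer(self, make_decoder):
        s = make_decoder(f0p=0.1, f1p=0.1)
        H.trisect_update(s, "outer")
        inner = np.interp(0.75, s.cdf.x, s.cdf.F) - np.interp(0.25, s.cdf.x, s.cdf.F)
        assert inner == pytest.approx(1.0 - 0.9, abs=1e-12)


class TestQary:
    def test_binary_reduction_identical_trajectories(self, rng):
        for _ in range(25):
            bits = rng.integers(0, 2, size=12)
            a = H.init_decoder(H.DecoderConfig(k=4, f0p=0.2, f1p=0.2))
            b = H.init_decoder(H.DecoderConfig(k=4, f0p=0.2, f1p=0.2))
            for bit in bits:
                H.update(a, int(bit))
                # q=2 with per-symbol error probabilities (f1', f0'):
                # receiving 0 wrongly means 1 was sent (prob f1')
                H.qary_update(b, int(bit), 2, (0.2, 0.2))
            np.testing.assert_allclose(a.cdf.F, b.cdf.F, atol=1e-12)
            np.testing.assert_allclose(a.cdf.x, b.cdf.x, atol=1e-12)

    def test_error_free_quaternary_drops_two_bits(self, make_decoder):
        s = make_decoder()
        H.qary_update(s, 2, 4, 0.0)
        assert H.entropy(s) == pytest.approx(-2.0, abs=1e-12)
        H.qary_update(s, 1, 4, 0.0)
        assert H.entropy(s) == pytest.approx(-4.0, abs=1e-12)

    def test_uniform_confusion_is_uninformative(self, make_decoder):
        s = make_decoder()
        H.qary_update(s, 3, 4, 0.75)
        masses = [np.interp((j + 1) / 4, s.cdf.x, s.cdf.F)
                  - np.interp(j / 4, s.cdf.x, s.cdf.F) for j in range(4)]
        np.testing.assert_allclose(masses, 0.25, atol=1e-12)

    def test_symbol_out_of_range(self, make_decoder):
        with pytest.raises(ValueError):
            H.qary_update(make_decoder(), 4, 4, 0.1)


class TestUndo:
    def test_zero_undo_is_noop(self, make_decoder):
        s = make_decoder()
        H.update(s, 0)
        x, F = s.cdf.x.copy(), s.cdf.F.copy()
        H.undo(s, 0.0)
        np.testing.assert_array_equal(s.cdf.x, x)
        np.testing.assert_array_equal(s.cdf.F, F)

    def test_full_undo_restores_prior(self, make_decoder):
        s = make_decoder(f0p=0.1, f1p=0.1)
        for b in [0, 1, 0, 0]:
            H.update(s, b)
        H.undo(s, 100.0)
        assert H.entropy(s) == pytest.approx(0.0, abs=1e-12)
        assert s.inputs_consumed == 0
        assert len(s.snapshots) == 1

    def test_whole_step_undo(self, make_decoder):
        s = make_decoder(f0p=0.0, f1p=0.0)
        for b in [0, 1, 0]:
            H.update(s, b)
        snap_x = s.snapshots[2][1].x.copy()
        H.undo(s, 1.0)
        assert H.entropy(s) == pytest.approx(-2.0, abs=1e-9)
        np.testing.assert_allclose(s.cdf.x, snap_x, atol=1e-12)
        assert s.inputs_consumed == 2
        assert len(s.snapshots) == 3

    @pytest.mark.parametrize("h_r", [0.3, 0.5, 1.2, 1.7])
    def test_fractional_undo_removes_exact_information(self, make_decoder, h_r):
        s = make_decoder(f0p=0.1, f1p=0.1)
        for b in [0, 0, 1, 0]:
            H.update(s, b)
        before = H.accumulated_information(s)
        H.undo(s, h_r)
        assert H.accumulated_information(s) == pytest.approx(before - h_r, abs=1e-6)
        assert len(s.snapshots) == s.inputs_consumed + 1

    def test_negative_reversal_rejected(self, make_decoder):
        with pytest.raises(ValueError):
            H.undo(make_decoder(), -1.0)


class TestSerialisation:
    def test_state_json_roundtrip(self, make_decoder, rng):
        s = make_decoder(f0p=0.15, f1p=0.25)
        for _ in range(8):
            H.update(s, int(rng.integers(2)))
        s2 = H.DecoderState.from_json(s.to_json())
        np.testing.assert_allclose(s2.cdf.x, s.cdf.x)
        np.testing.assert_allclose(s2.cdf.F, s.cdf.F)
        assert s2.inputs_consumed == s.inputs_consumed
        assert s2.config == s.config
        assert len(s2.snapshots) == len(s.snapshots)
        # resumed session behaves identically
        H.update(s, 1)
        H.update(s2, 1)
        np.testing.assert_allclose(s2.cdf.F, s.cdf.F, atol=1e-15)
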