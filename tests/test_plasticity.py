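"""Learning dynamics: currents, single steps, online training, the energy
function, and the exact coding-equivalence properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparseperceptron import (PatternSet, PlasticityConfig, SynapticState,
                              energy, gen_patterns, plasticity_step,
                              postsynaptic_current, train_online)


class TestPostsynapticCurrent:
    def test_zero_weights_give_negative_threshold(self):
        s = SynapticState(np.zeros(4), theta=1.0)
        assert postsynaptic_current(s, np.ones(4)) == pytest.approx(-2.0)

    def test_direct_evaluation(self):
        s = SynapticState(np.array([1.0, 1.0]), theta=1.0)
        h = postsynaptic_current(s, np.array([1.0, -1.0]))
        assert h == pytest.approx(-np.sqrt(2.0))

    def test_dimension_mismatch_rejected(self):
        s = SynapticState(np.zeros(4))
        with pytest.raises(ValueError):
            postsynaptic_current(s, np.ones(3))

    def test_binary_current_equals_zeromean_current(self):
        # h = Σw·x − γ with γ = f·Σw + θ_f√N is an algebraic identity with
        # the zero-mean model on z = x − f, for any weights
        rng = np.random.default_rng(0)
        w = rng.random(64)
        f = 0.5
        z = np.where(rng.random(64) < f, 1 - f, -f)
        x = z + f
        sb = SynapticState(w, theta=1.0, f=f, coding="binary01")
        sz = SynapticState(w, theta=1.0, f=f, coding="zeromean_f")
        assert postsynaptic_current(sb, x) == pytest.approx(
            postsynaptic_current(sz, z), abs=1e-10)


class TestPlasticityStep:
    def test_depression_is_rectified_from_tabula_rasa(self):
        s = SynapticState(np.zeros(3), theta=1.0)
        cfg = PlasticityConfig(epsilon=0.1, lam=0.0)
        out = plasticity_step(s, np.array([1.0, -1.0, 1.0]), cfg)
        assert np.allclose(out.w, [0.1, 0.0, 0.1])
        assert np.all(s.w == 0)  # input untouched

    def test_imbalance_shrinks_potentiation(self):
        s = SynapticState(np.zeros(3), theta=1.0)
        cfg = PlasticityConfig(epsilon=0.1, lam=0.5)
        out = plasticity_step(s, np.array([1.0, -1.0, 1.0]), cfg)
        assert np.allclose(out.w, [0.05, 0.0, 0.05])

    def test_decay_variant_depresses_after_firing(self):
        # fired case: uniform decay −ελ, clamped at zero
        s = SynapticState(np.array([0.2, 0.05]), theta=0.0)
        cfg = PlasticityConfig(epsilon=0.1, lam=0.5,
                               rule_variant="decay_when_fired")
        out = plasticity_step(s, np.array([1.0, 1.0]), cfg)
        assert np.allclose(out.w, [0.15, 0.0])

    def test_stop_all_variant_freezes_after_firing(self):
        s = SynapticState(np.array([0.2, 0.05]), theta=0.0)
        cfg = PlasticityConfig(epsilon=0.1, lam=0.5)
        out = plasticity_step(s, np.array([1.0, 1.0]), cfg)
        assert np.array_equal(out.w, s.w)

    def test_invalid_imbalance_rejected(self):
        with pytest.raises(ValueError):
            PlasticityConfig(epsilon=0.1, lam=1.5)

    def test_reparametrisation_identity(self):
        # a = ε(1−λ), b = ε(1+λ); a = b ⇔ λ = 0
        cfg = PlasticityConfig.from_ab(0.05, 0.15)
        assert cfg.epsilon == pytest.approx(0.1)
        assert cfg.lam == pytest.approx(0.5)
        assert cfg.a == pytest.approx(0.05)
        assert cfg.b == pytest.approx(0.15)
        assert PlasticityConfig.from_ab(0.1, 0.1).lam == 0.0


class TestTrainOnline:
    def test_single_all_high_pattern_closed_form(self):
        # every update adds ε to all weights: h = mεN − θ√N, so the unit
        # fires after exactly ceil(θ√N/(εN)) updates; ε = 1/128 keeps the
        # arithmetic exact in binary floating point
        N, eps = 100, 1.0 / 128.0
        patterns = PatternSet(np.ones((1, N)))
        cfg = PlasticityConfig(epsilon=eps, lam=0.0, theta=1.0, seed=0)
        res = train_online(patterns, cfg)
        assert res.converged
        assert res.updates == int(np.ceil(np.sqrt(N) / (eps * N)))  # = 13

    def test_converges_below_capacity(self):
        patterns = gen_patterns(200, 100, seed=3)  # α = 0.5
        cfg = PlasticityConfig(epsilon=1 / 200, lam=0.0, max_epochs=3000,
                               seed=4)
        res = train_online(patterns, cfg)
        assert res.converged
        probe = patterns.data @ res.state.w - np.sqrt(200)
        assert np.all(probe >= 0)

    def test_excessive_imbalance_fails_to_converge(self):
        patterns = gen_patterns(100, 80, seed=5)  # α = 0.8
        cfg = PlasticityConfig(epsilon=1 / 100, lam=0.99, max_epochs=300,
                               seed=6)
        res = train_online(patterns, cfg)
        assert not res.converged
        assert res.epochs == 300

    def test_nonzero_initial_weights_supported(self):
        patterns = gen_patterns(100, 10, seed=7)
        cfg = PlasticityConfig(epsilon=0.01, lam=0.0, max_epochs=2000, seed=8)
        w0 = np.full(100, 0.05)
        res = train_online(patterns, cfg, w0=w0)
        assert res.converged
        assert np.all(res.state.w >= 0)


class TestEnergy:
    def test_tabula_rasa_energy(self):
        patterns = gen_patterns(16, 5, seed=0)
        s = SynapticState(np.zeros(16), theta=1.0)
        assert energy(s, patterns, lam=0.3) == pytest.approx(5 * 4.0)

    def test_feasible_state_pays_only_the_l1_term(self):
        patterns = PatternSet(np.ones((3, 4)))
        s = SynapticState(np.full(4, 10.0), theta=1.0)
        assert energy(s, patterns, lam=0.5) == pytest.approx(0.5 * 40.0)

    def test_direct_evaluation(self):
        patterns = PatternSet(np.array([[1.0, -1.0]]))
        s = SynapticState(np.array([1.0, 0.0]), theta=1.0)
        expected = (np.sqrt(2) - 1.0) + 0.5 * 1.0
        assert energy(s, patterns, lam=0.5) == pytest.approx(expected)

    def test_decay_variant_descends_the_energy(self):
        patterns = gen_patterns(100, 10, seed=1)
        lam = 0.2
        cfg = PlasticityConfig(epsilon=0.01, lam=lam, max_epochs=3000,
                               rule_variant="decay_when_fired", seed=2)
        res = train_online(patterns, cfg)
        assert res.converged
        e0 = energy(SynapticState(np.zeros(100)), patterns, lam)
        assert energy(res.state, patterns, lam) <= e0


class TestCodingEquivalence:
    """The f = 1/2 zero-mean model under (ε, λ) must reproduce the bipolar
    model under (ε/2, 2λ) exactly, and the 0/1 model with the adaptive
    threshold γ must follow the zero-mean model decision for decision.
    All parameters are binary-representable so trajectories match bitwise.
    """

    @pytest.mark.parametrize("variant", ["stop_all", "decay_when_fired"])
    def test_zeromean_matches_bipolar_trajectory(self, variant):
        N, K = 32, 8
        bip = gen_patterns(N, K, seed=42)
        zm = PatternSet(bip.data / 2.0, coding="zeromean_f", f=0.5)
        cfg_z = PlasticityConfig(epsilon=1 / 64, lam=0.25, theta=1.0, f=0.5,
                                 rule_variant=variant, max_epochs=500, seed=9)
        cfg_b = PlasticityConfig(epsilon=1 / 128, lam=0.5, theta=1.0,
                                 rule_variant=variant, max_epochs=500, seed=9)
        rz = train_online(zm, cfg_z)
        rb = train_online(bip, cfg_b)
        # the two runs must be indistinguishable step for step, whether or
        # not the imbalance admits convergence at this load
        assert rz.converged == rb.converged
        assert rz.updates == rb.updates
        assert np.array_equal(rz.state.w, rb.state.w)

    @pytest.mark.parametrize("variant", ["stop_all", "decay_when_fired"])
    def test_binary_adaptive_threshold_matches_zeromean(self, variant):
        N, K, f = 16, 6, 0.5
        zm = gen_patterns(N, K, coding="zeromean_f", f=f, seed=17)
        bin01 = PatternSet(zm.data + f, coding="binary01", f=f)
        cfg = PlasticityConfig(epsilon=1 / 64, lam=0.25, theta=1.0, f=f,
                               rule_variant=variant, max_epochs=500, seed=3)
        rz = train_online(zm, cfg)
        rb = train_online(bin01, cfg)
        assert rz.converged == rb.converged
        assert rz.updates == rb.updates
        assert np.array_equal(rz.state.w, rb.state.w)


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 2 ** 20), lam=st.floats(0.0, 1.0),
       fired_theta=st.floats(0.0, 2.0))
def test_property_steps_preserve_nonnegativity(seed, lam, fired_theta):
    rng = np.random.default_rng(seed)
    w = rng.random(20) * 0.1
    s = SynapticState(w, theta=fired_theta)
    cfg = PlasticityConfig(epsilon=0.05, lam=lam,
                           rule_variant="decay_when_fired")
    x = np.where(rng.random(20) < 0.5, 1.0, -1.0)
    out = plasticity_step(s, x, cfg)
    assert np.all(out.w >= 0)
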