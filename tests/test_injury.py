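"""Injury transforms versus naive per-spike reference implementations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dorsalhorn as dh
from dorsalhorn.injury import InjuryRule

from conftest import random_small_train
from test_spike_trains import constant_rate


# --- naive reference implementations (independent oracles) -----------------

def naive_evoke(times, p, k, spacing, rng):
    out = []
    for t in times:
        out.append(t)
        if rng.random() < p:
            for j in range(1, k + 1):
                out.append(t + j * spacing)
    return np.array(sorted(set(out)))


def naive_block(times, omega, phase):
    period = 2 * np.pi / omega
    out = []
    for t in times:
        if ((t - phase) % period) < period / 2:
            out.append(t)
    return np.array(out)


def naive_refractory(times, tau):
    out = []
    for t in times:
        if not out or t - out[-1] >= tau:
            out.append(t)
    return np.array(out)


# --- evoked potentials -----------------------------------------------------

class TestEvokedPotentials:
    def test_zero_extra_spikes_is_identity(self):
        tr = dh.SpikeTrain(np.array([1.0, 5.0, 9.0]))
        out = dh.evoke_potentials(tr, p_evoke=0.5, k_extra=0, rng=0)
        np.testing.assert_allclose(out.times, tr.times)

    def test_certain_burst(self):
        tr = dh.SpikeTrain(np.array([10.0]))
        out = dh.evoke_potentials(tr, p_evoke=1.0, k_extra=2, spacing=1.0, rng=0)
        np.testing.assert_allclose(out.times, [10.0, 11.0, 12.0])

    def test_expected_count_multiplier(self):
        # p=0.2, k=2: E|y| = |x| * 1.4 (before rare merge collisions)
        n_in = n_out = 0
        for seed in range(150):
            tr = dh.generate_fiber_spikes(constant_rate(50.0, 2000.0), 2000.0, rng=seed)
            out = dh.evoke_potentials(tr, 0.2, 2, spacing=2.0, rng=seed + 10_000)
            n_in += len(tr)
            n_out += len(out)
    # ~15000 input spikes: Monte-Carlo error well under 3%
        assert n_out / n_in == pytest.approx(1.4, rel=0.03)

    def test_output_contains_input(self, rng):
        for _ in range(50):
            tr = random_small_train(rng)
            out = dh.evoke_potentials(tr, 0.5, 3, rng=rng)
            assert set(np.round(tr.times, 9)) <= set(np.round(out.times, 9))


# --- intermittent blocking -------------------------------------------------

class TestIntermittentBlock:
    def test_train_in_passing_phase_is_kept(self):
        # period 40 ms: [0, 20) passes
        tr = dh.SpikeTrain(np.array([1.0, 10.0, 19.0]))
        out = dh.intermittent_block(tr, omega=np.pi / 20)
        np.testing.assert_allclose(out.times, tr.times)

    def test_train_in_blocking_phase_is_deleted(self):
        tr = dh.SpikeTrain(np.array([21.0, 30.0, 39.0]))
        out = dh.intermittent_block(tr, omega=np.pi / 20)
        assert len(out) == 0

    def test_gate_evaluation(self):
        # omega = pi rad/ms -> period 2 ms; [0,1) passes, [1,2) blocks
        tr = dh.SpikeTrain(np.array([0.5, 1.5, 2.5]))
        out = dh.intermittent_block(tr, omega=np.pi)
        np.testing.assert_allclose(out.times, [0.5, 2.5])

    def test_phase_offset_shifts_gate(self):
        tr = dh.SpikeTrain(np.array([0.5, 1.5, 2.5]))
        out = dh.intermittent_block(tr, omega=np.pi, phase_offset=1.0)
        np.testing.assert_allclose(out.times, [1.5])

    def test_removes_half_of_stationary_train(self):
        tr = dh.generate_fiber_spikes(constant_rate(100.0, 200_000.0), 200_000.0, rng=5)
        out = dh.intermittent_block(tr, omega=10.0)
        assert len(out) / len(tr) == pytest.approx(0.5, abs=0.03)


# --- increased refractoriness ----------------------------------------------

class TestRefractoriness:
    def test_zero_tau_is_identity(self):
        tr = dh.SpikeTrain(np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(dh.increase_refractoriness(tr, 0.0).times, tr.times)

    def test_sequential_scan(self):
        tr = dh.SpikeTrain(np.array([0.0, 5.0, 12.0, 30.0]))
        out = dh.increase_refractoriness(tr, 10.0)
        np.testing.assert_allclose(out.times, [0.0, 12.0, 30.0])

    def test_dead_time_modified_rate(self):
        # r = 100 Hz, tau = 10 ms -> surviving rate r/(1+r*tau) = 50 Hz
        duration = 1.0e6  # ms -> 1e5 expected input spikes
        tr = dh.generate_fiber_spikes(constant_rate(100.0, duration), duration, rng=7)
        out = dh.increase_refractoriness(tr, 10.0)
        rate = len(out) / (duration * 1e-3)
        assert rate == pytest.approx(50.0, rel=0.02)

    def test_higher_rates_attenuated_more(self):
        # frequency dependence: deleted fraction grows with input rate
        deleted = {}
        for r in (20.0, 100.0):
            n_in = n_out = 0
            for seed in range(100):
                tr = dh.generate_fiber_spikes(constant_rate(r, 5000.0), 5000.0, rng=seed)
                n_in += len(tr)
                n_out += len(dh.increase_refractoriness(tr, 10.0))
            deleted[r] = 1.0 - n_out / n_in
        assert deleted[100.0] > deleted[20.0]


# --- delay and dispatch ----------------------------------------------------

class TestDelayAndDispatch:
    def test_delay_trivials(self):
        tr = dh.SpikeTrain(np.array([1.0, 2.0]))
        np.testing.assert_allclose(dh.delay_train(tr, 0.0).times, [1.0, 2.0])
        np.testing.assert_allclose(dh.delay_train(tr, 125.0).times, [126.0, 127.0])
        assert len(dh.delay_train(dh.SpikeTrain(np.empty(0)), 50.0)) == 0

    def test_dispatch_none_is_identity(self):
        tr = dh.SpikeTrain(np.array([3.0, 8.0]))
        out = dh.apply_rule(tr, InjuryRule(variant="none"), rng=0)
        np.testing.assert_allclose(out.times, tr.times)

    def test_dispatch_total_block_empties(self):
        tr = dh.SpikeTrain(np.array([3.0, 8.0]))
        assert len(dh.apply_rule(tr, InjuryRule(variant="total_block"), rng=0)) == 0

    def test_dispatch_refractory_matches_direct_call(self):
        tr = dh.SpikeTrain(np.array([0.0, 5.0, 12.0, 30.0]))
        out = dh.apply_rule(tr, InjuryRule(variant="refractory", tau=10.0), rng=0)
        np.testing.assert_allclose(out.times, [0.0, 12.0, 30.0])

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            InjuryRule(variant="reflection")
        with pytest.raises(ValueError):
            InjuryRule.from_dict({"variant": "evoked", "bogus": 1})

    def test_rule_dict_round_trip(self):
        rule = InjuryRule(variant="evoked", p_evoke=0.2, k_extra=2, spacing=2.0)
        assert InjuryRule.from_dict(rule.to_dict()) == rule


# --- injury assignment -----------------------------------------------------

class TestAssignInjuries:
    def test_extreme_fractions(self):
        assert dh.assign_injuries(100, 0.0, rng=0).size == 0
        assert np.array_equal(dh.assign_injuries(5, 1.0, rng=0), np.arange(5))

    def test_rounding(self):
        assert dh.assign_injuries(380, 0.5, rng=0).size == 190
        # round half away from zero: 0.25 * 2 = 0.5 -> 1
        assert dh.assign_injuries(2, 0.25, rng=0).size == 1

    def test_deterministic_and_distinct(self):
        a = dh.assign_injuries(50, 0.4, rng=np.random.default_rng(9))
        b = dh.assign_injuries(50, 0.4, rng=np.random.default_rng(9))
        assert np.array_equal(a, b)
        assert np.unique(a).size == a.size


# --- structural invariants and oracle equivalence --------------------------

RULESETS = [
    ("evoked", dict(p_evoke=0.3, k_extra=2, spacing=2.0)),
    ("block", dict(omega=np.pi / 20, phase_offset=0.0)),
    ("refractory", dict(tau=10.0)),
    ("delay", dict(d=125.0)),
    ("none", {}),
    ("total_block", {}),
]


@pytest.mark.parametrize("variant,params", RULESETS)
def test_transforms_preserve_ordering_and_nonnegativity(variant, params, rng):
    rule = InjuryRule(variant=variant, **params)
    for _ in range(100):
        tr = random_small_train(rng)
        out = dh.apply_rule(tr, rule, rng=rng)
        assert np.all(out.times >= 0)
        if len(out) > 1:
            assert np.all(np.diff(out.times) > 0)
        if variant in ("block", "refractory", "total_block"):
            assert set(np.round(out.times, 9)) <= set(np.round(tr.times, 9))


def test_oracle_equivalence_on_random_trains(rng):
    """Every transform matches its naive per-spike reference on 1000 trains."""
    for i in range(1000):
        tr = random_small_train(rng)
        seed = 77_000 + i

        got = dh.evoke_potentials(tr, 0.3, 2, spacing=2.0, rng=np.random.default_rng(seed))
        # reference consumes the RNG identically: one uniform per input spike
        ref_rng = np.random.default_rng(seed)
        draws = ref_rng.random(len(tr))
        ref = []
        for t, u in zip(tr.times, draws):
            ref.append(t)
            if u < 0.3:
                ref += [t + 2.0, t + 4.0]
        np.testing.assert_array_equal(got.times, np.unique(np.array(sorted(set(ref)))))

        np.testing.assert_array_equal(
            dh.intermittent_block(tr, np.pi / 20, 3.0).times,
            naive_block(tr.times, np.pi / 20, 3.0),
        )
        np.testing.assert_array_equal(
            dh.increase_refractoriness(tr, 7.5).times, naive_refractory(tr.times, 7.5)
        )
        np.testing.assert_array_equal(dh.delay_train(tr, 12.5).times, tr.times + 12.5)


@settings(max_examples=50, derandomize=True)
@given(
    times=st.lists(
        st.floats(min_value=0.0, max_value=1000.0, allow_nan=False), min_size=0, max_size=20
    ),
    tau=st.floats(min_value=0.0, max_value=50.0),
)
def test_refractory_matches_reference_property(times, tau):
    t = np.unique(np.asarray(times))
    tr = dh.SpikeTrain(t)
    np.testing.assert_array_equal(
        dh.increase_refractoriness(tr, tau).times, naive_refractory(t, tau)
    )
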