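"""Stimulus construction, the simulation loop, and phase extraction."""

import numpy as np
import pytest

from streamclass import (
    GNShape,
    INTEGRATION,
    SEGREGATION,
    ModelConfig,
    extract_phases,
    init_mixture,
    make_sequence,
    run_deterministic,
    run_stochastic,
    step,
)
from streamclass.engine import run_batch


class TestMakeSequence:
    def test_aba_triplet_order(self):
        seq = make_sequence("ABA-", delta=5.0, n_triplets=2)
        assert list(seq.labels) == ["A", "B", "A", "A", "B", "A"]
        np.testing.assert_array_equal(seq.features, [0, 5, 0, 0, 5, 0])

    def test_abab_alternation(self):
        seq = make_sequence("ABAB", delta=1.0, n_triplets=2)
        assert list(seq.labels) == ["A", "B", "A", "B"]

    def test_zero_separation(self):
        seq = make_sequence("ABA-", delta=0.0, n_triplets=3)
        assert np.all(seq.features == 0.0)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            make_sequence("AB-", delta=1.0, n_triplets=1)


class TestInitMixture:
    @pytest.mark.parametrize("delta,pi2", [(0.6, 0.0001), (5.0, 0.001)])
    def test_two_classes_at_tones(self, delta, pi2):
        shape = GNShape(beta=0.5, sigma=1.0)
        state = init_mixture(delta, shape, pi2)
        np.testing.assert_array_equal(state.centroids, [0.0, delta])
        np.testing.assert_allclose(state.mixing, [1 - pi2, pi2])
        assert state.mixing.sum() == pytest.approx(1.0)

    def test_invalid_pi2(self):
        with pytest.raises(ValueError):
            init_mixture(1.0, GNShape(beta=2.0), 0.0)


class TestStep:
    def test_frozen_dynamics(self, rng):
        shape = GNShape(beta=1.5, sigma=1.0)
        state = init_mixture(5.0, shape, 0.0001)
        cfg = ModelConfig(gamma=0.0, eta=0.0, theta=0.0)
        new, k, post = step(state, 5.0, cfg)
        np.testing.assert_array_equal(new.centroids, state.centroids)
        np.testing.assert_array_equal(new.mixing, state.mixing)

    def test_b_element_wins_class1_but_boosts_pi2(self):
        # prior dominance beats likelihood: B classified to class 1 while
        # the mixing probability of class 2 grows (hand-computed oracle)
        from streamclass import gnorm_pdf

        shape = GNShape(beta=1.5, sigma=1.0)
        state = init_mixture(5.0, shape, 0.0001)
        cfg = ModelConfig(gamma=0.1, eta=0.5)
        p_b1 = gnorm_pdf(5.0, 0.0, shape)
        p_b2 = gnorm_pdf(5.0, 5.0, shape)
        assert p_b2 > p_b1  # likelihood favors class 2
        new, k, post = step(state, 5.0, cfg)
        assert k == 0      # posterior favors class 1
        assert new.mixing[1] > state.mixing[1]

    def test_a_element_decreases_pi2(self):
        shape = GNShape(beta=1.5, sigma=1.0)
        state = init_mixture(5.0, shape, 0.0001)
        cfg = ModelConfig(gamma=0.1, eta=0.5)
        new, k, _ = step(state, 0.0, cfg)
        assert k == 0
        assert new.mixing[1] < state.mixing[1]


class TestRunDeterministic:
    def test_reference_run_becomes_periodic(self):
        # gamma=0.1, eta=0.5, delta=5, beta=1.5: after a transient the
        # switching intervals settle into a fixed alternating pattern
        shape = GNShape(beta=1.5, sigma=1.0)
        seq = make_sequence("ABA-", 5.0, 1500)
        tr = run_deterministic(ModelConfig(gamma=0.1, eta=0.5), seq,
                               shape=shape, pi2_init=0.001)
        intervals = np.diff(tr.switch_indices)
        assert len(intervals) > 20
        tail = intervals[-12:]
        assert np.array_equal(tail[::2], np.full(6, tail[0]))
        assert np.array_equal(tail[1::2], np.full(6, tail[1]))

    def test_zero_separation_never_switches(self):
        shape = GNShape(beta=0.5, sigma=1.0)
        seq = make_sequence("ABA-", 0.0, 500)
        tr = run_deterministic(ModelConfig(gamma=0.1, eta=0.05), seq,
                               shape=shape, pi2_init=0.001)
        assert len(tr.switch_indices) == 0
        assert np.all(tr.percepts == INTEGRATION)

    def test_large_separation_starts_segregated(self):
        shape = GNShape(beta=0.5, sigma=1.0)
        seq = make_sequence("ABA-", 9.0, 100)
        tr = run_deterministic(ModelConfig(gamma=0.1, eta=0.05), seq,
                               shape=shape, pi2_init=0.001)
        assert tr.percepts[1] == SEGREGATION  # first B captured by class 2

    def test_switch_crossings_near_half(self):
        # deterministic switches happen where P(c=2|B) crosses 0.5
        shape = GNShape(beta=1.5, sigma=1.0)
        seq = make_sequence("ABA-", 5.0, 1500)
        tr = run_deterministic(ModelConfig(gamma=0.1, eta=0.5), seq,
                               shape=shape, pi2_init=0.001)
        b_idx, ev = tr.evidence_series()
        ev_by_idx = dict(zip(b_idx, ev))
        checked = 0
        for s in tr.switch_indices[5:]:
            if s in ev_by_idx:
                prev_bs = b_idx[b_idx < s]
                if len(prev_bs):
                    jump = abs(ev_by_idx[s] - ev_by_idx[prev_bs[-1]])
                    assert abs(ev_by_idx[s] - 0.5) <= jump + 1e-12
                    checked += 1
        assert checked > 10

    def test_mu2_pinned_and_pi_complementary(self):
        # no A is ever classified to class 2 in the reference run, so its
        # centroid never leaves B; and pi1 = 1 - pi2 throughout
        shape = GNShape(beta=1.5, sigma=1.0)
        seq = make_sequence("ABA-", 5.0, 400)
        tr = run_deterministic(ModelConfig(gamma=0.1, eta=0.5), seq,
                               shape=shape, pi2_init=0.001)
        a_to_class2 = any(r.k_star == 1 and r.label == "A" for r in tr.records)
        assert not a_to_class2
        for r in tr.records:
            assert r.centroids[1] == pytest.approx(5.0, abs=1e-12)
            assert r.mixing[0] == pytest.approx(1 - r.mixing[1], abs=1e-12)


class TestRunStochastic:
    def test_k1_percept_follows_last_b(self, rng):
        shape = GNShape(beta=0.5, sigma=1.0)
        seq = make_sequence("ABA-", 0.6, 300)
        cfg = ModelConfig(gamma=0.03, eta=0.1, classification_mode="stochastic", K=1)
        tr, _ = run_stochastic(cfg, seq, rng, shape=shape, pi2_init=0.0001)
        last_b_class = None
        for r, percept in zip(tr.records, tr.percepts):
            if r.label == "B":
                last_b_class = r.k_star
            if last_b_class is not None:
                assert percept == (SEGREGATION if last_b_class == 1 else INTEGRATION)

    def test_forced_posterior_reproduces_deterministic(self):
        # huge separation makes every posterior effectively {0, 1}; the
        # K=1 stochastic run then retraces the deterministic one
        shape = GNShape(beta=2.0, sigma=0.01)
        seq = make_sequence("ABA-", 2.0, 300)
        det = run_deterministic(ModelConfig(gamma=0.1, eta=0.001), seq,
                                shape=shape, pi2_init=0.3)
        sto, _ = run_stochastic(
            ModelConfig(gamma=0.1, eta=0.001, classification_mode="stochastic", K=1),
            seq, np.random.default_rng(0), shape=shape, pi2_init=0.3)
        assert [r.k_star for r in det.records] == [r.k_star for r in sto.records]
        np.testing.assert_array_equal(det.percepts, sto.percepts)

    def test_reproducible_given_seed(self):
        shape = GNShape(beta=0.5, sigma=1.0)
        seq = make_sequence("ABA-", 0.6, 400)
        cfg = ModelConfig(gamma=0.03, eta=0.1, classification_mode="stochastic", K=6)
        t1, _ = run_stochastic(cfg, seq, np.random.default_rng(7), shape=shape)
        t2, _ = run_stochastic(cfg, seq, np.random.default_rng(7), shape=shape)
        np.testing.assert_array_equal(t1.percepts, t2.percepts)
        assert [r.k_star for r in t1.records] == [r.k_star for r in t2.records]

    def test_drawn_update_source_differs(self):
        shape = GNShape(beta=0.5, sigma=1.0)
        seq = make_sequence("ABA-", 0.6, 900)
        base = dict(gamma=0.03, eta=0.1, classification_mode="stochastic", K=6)
        tp, _ = run_stochastic(ModelConfig(**base, update_source="percept"),
                               seq, np.random.default_rng(3), shape=shape)
        td, _ = run_stochastic(ModelConfig(**base, update_source="drawn"),
                               seq, np.random.default_rng(3), shape=shape)
        assert not np.array_equal(
            [r.mixing[1] for r in tp.records], [r.mixing[1] for r in td.records]
        )


class TestExtractPhases:
    def _trace_from_percepts(self, percepts):
        from streamclass.simulate import SimulationTrace, StepRecord

        records = [
            StepRecord(i, "B", 1.0, 0, np.array([0.6, 0.4]),
                       np.array([0.9, 0.1]), np.array([0.0, 1.0]))
            for i in range(len(percepts))
        ]
        p = np.asarray(percepts)
        switches = np.flatnonzero(np.diff(p) != 0) + 1
        return SimulationTrace(records, p, switches, ModelConfig(), None)

    def test_tiling_and_boundaries(self):
        tr = self._trace_from_percepts([1, 1, 1, 2, 2, 1, 1])
        phases = extract_phases(tr)
        assert [p.duration for p in phases] == [3, 2, 2]
        assert [p.boundary for p in phases] == [True, False, True]
        interior = [p for p in phases if not p.boundary]
        assert len(interior) == 1 and interior[0].percept == 2

    def test_constant_stream_single_boundary_phase(self):
        tr = self._trace_from_percepts([1] * 6)
        phases = extract_phases(tr)
        assert len(phases) == 1 and phases[0].boundary

    def test_durations_sum_to_trace_length(self, rng):
        percepts = rng.choice([1, 2], size=40)
        phases = extract_phases(self._trace_from_percepts(percepts))
        assert sum(p.duration for p in phases) == 40


class TestEngineEquivalence:
    def test_stochastic_single_run_matches_scalar(self):
        shape = GNShape(beta=0.5, sigma=1.0)
        seq = make_sequence("ABA-", 0.6, 500)
        cfg = ModelConfig(gamma=0.03, eta=0.1, classification_mode="stochastic", K=6)
        tr, phases = run_stochastic(cfg, seq, np.random.default_rng(3),
                                    shape=shape, pi2_init=1e-4)
        res = run_batch(gamma=0.03, eta=0.1, delta=0.6, sigma=1.0, beta=0.5,
                        pi2_init=1e-4, mode="stochastic", K=6,
                        n_phases=10 ** 9, max_elements=len(seq),
                        rng=np.random.default_rng(3))
        rp = res.phases[0]
        scalar_interior = [p for p in phases if not p.boundary]
        closed = rp.n_switches
        assert closed > 5
        np.testing.assert_array_equal(
            rp.durations[1:], [p.duration for p in scalar_interior][: closed - 1]
        )
        np.testing.assert_allclose(
            rp.evidence[1:],
            [p.evidence_at_start for p in scalar_interior][: closed - 1],
            atol=1e-12,
        )

    def test_deterministic_single_run_matches_scalar(self):
        shape = GNShape(beta=1.5, sigma=1.0)
        seq = make_sequence("ABA-", 5.0, 600)
        det = run_deterministic(ModelConfig(gamma=0.1, eta=0.5), seq,
                                shape=shape, pi2_init=0.001)
        res = run_batch(gamma=0.1, eta=0.5, delta=5.0, sigma=1.0, beta=1.5,
                        pi2_init=0.001, mode="deterministic",
                        n_phases=10 ** 9, max_elements=len(seq))
        rp = res.phases[0]
        scalar_phases = extract_phases(det)
        np.testing.assert_array_equal(
            rp.durations, [p.duration for p in scalar_phases[: rp.n_switches]]
        )

    def test_scale_invariance_of_dynamics(self):
        # (delta, sigma, eta) and (delta/s, sigma/s, eta/s) give identical
        # classification sequences
        base = run_batch(gamma=0.1, eta=0.05, delta=3.0, sigma=1.0, beta=0.5,
                         pi2_init=0.001, mode="deterministic",
                         n_phases=40, max_elements=40_000)
        for s in (2.0, 10.0):
            scaled = run_batch(gamma=0.1, eta=0.05 / s, delta=3.0 / s, sigma=1.0 / s,
                               beta=0.5, pi2_init=0.001, mode="deterministic",
                               n_phases=40, max_elements=40_000)
            np.testing.assert_array_equal(base.phases[0].durations,
                                          scaled.phases[0].durations)

    def test_batch_reproducibility(self):
        kw = dict(gamma=[0.03, 0.1], eta=[0.1, 0.2], delta=0.6, sigma=1.0,
                  beta=0.5, pi2_init=1e-4, mode="stochastic", K=6,
                  n_phases=50, max_elements=30_000)
        r1 = run_batch(**kw, rng=np.random.default_rng(9))
        r2 = run_batch(**kw, rng=np.random.default_rng(9))
        for a, b in zip(r1.phases, r2.phases):
            np.testing.assert_array_equal(a.durations, b.durations)
            np.testing.assert_array_equal(a.evidence, b.evidence)
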