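"""Experiment timelines: training trials, recall tests, analytic
fast-forwarding, event-driven equivalence and run determinism."""

import numpy as np
import pandas as pd
import pytest

from seqreplay import (ModelParams, NetworkState, PlasticityGates,
                       fast_forward, load_preset, run_experiment,
                       run_recall_test, run_training_trial, update_salience,
                       update_weights, step_network, instantiate_links)
from seqreplay.engine import SegmentRun
from seqreplay.protocol import (DaySpec, ExperimentSpec, InvalidSpecificationError,
                                TestSpec, TrainBlock, build_epochs)
from conftest import ABCDE, FORWARD, mean_forward


class TestTrainingTrial:
    def test_first_trial_allocates_items_and_directional_links(self, params):
        net = NetworkState()
        run_training_trial(net, ABCDE, params)
        assert net.catalog.labels == ABCDE
        cat = net.catalog
        for region in (net.ctx, net.hc):
            for pre, post in FORWARD:
                i, j = cat.index(pre), cat.index(post)
                assert region.exists[i, j]
                assert region.W[i, j] > region.W[j, i]

    def test_repeat_trial_adds_no_items_and_grows_forward_weights(self, params):
        net = NetworkState()
        run_training_trial(net, ABCDE, params)
        w1 = mean_forward(net.hc, net)
        n_links = net.hc.exists.sum()
        run_training_trial(net, ABCDE, params)
        assert len(net.catalog) == 5
        assert net.hc.exists.sum() >= n_links
        assert mean_forward(net.hc, net) > w1

    def test_single_item_sequence_never_links(self, params):
        net = NetworkState()
        for _ in range(3):
            run_training_trial(net, ("A",), params)
        assert not net.ctx.exists.any() and not net.hc.exists.any()

    def test_empty_sequence_rejected(self, params):
        with pytest.raises(ValueError):
            run_training_trial(NetworkState(), (), params)


class TestRecallTest:
    def test_untrained_network_recalls_cue_only(self, params):
        net = NetworkState()
        net.add_items(ABCDE)
        res = run_recall_test(net, "A", ABCDE, params)
        assert res.accuracy == 20.0
        assert res.recall_time == params.recall_ceiling
        assert {c for c, _ in res.crossings} == {"A"}

    def test_trained_network_full_ordered_recall(self, params, day1_network):
        net = day1_network.copy()
        res = run_recall_test(net, "A", ABCDE, params)
        assert res.accuracy == 100.0
        assert res.recall_time < params.recall_ceiling
        order = []
        for c, _ in res.crossings:
            if c not in order:
                order.append(c)
        assert tuple(order[:5]) == ABCDE

    def test_unknown_cue_rejected(self, params):
        net = NetworkState()
        net.add_items("AB")
        with pytest.raises(ValueError):
            run_recall_test(net, "Z", ("A", "B"), params)


class TestFastForward:
    def test_zero_gap_only_resets_transients(self, params):
        net = NetworkState()
        net.add_items("AB")
        net.ctx.a[:] = 0.4
        net.salience[:] = 5.0
        fast_forward(net, 0.0, params)
        assert np.all(net.ctx.a == 0) and np.all(net.salience == 5.0)

    def test_twelve_hour_salience_decay(self, params):
        net = NetworkState()
        net.add_items("A")
        net.salience[0] = 1000.0
        fast_forward(net, 43_200.0, params)
        assert net.salience[0] == pytest.approx(1000.0 * np.exp(-0.5))

    def test_negative_gap_rejected(self, params):
        with pytest.raises(ValueError):
            fast_forward(NetworkState(), -1.0, params)

    def test_sixty_second_gap_matches_euler_oracle_on_weights(self, params):
        # brute-force Euler integration of the idle gap (zero input)
        net = NetworkState()
        run_training_trial(net, ABCDE, params)
        SegmentRun(net, params).run(params.settle_duration)
        euler = net.copy()
        skip = net.copy()
        drive = np.zeros(euler.n)
        for _ in range(50_000):
            a_c, a_h = euler.ctx.a.copy(), euler.hc.a.copy()
            _, d_c, d_h = step_network(euler, drive, params)
            update_weights(euler.ctx, a_c, d_c, params)
            update_weights(euler.hc, a_h, d_h, params)
            update_salience(euler, params)
        fast_forward(skip, 50.0, params)
        np.testing.assert_allclose(skip.ctx.W, euler.ctx.W,
                                   rtol=1e-5, atol=1e-12)
        np.testing.assert_allclose(skip.hc.W, euler.hc.W,
                                   rtol=1e-5, atol=1e-12)


def test_event_driven_matches_continuous_integration(params):
    """One hour with a trial, a long gap, and a recall test: skipping the
    gap analytically reproduces full Euler integration on all weights."""
    gates = PlasticityGates()

    cont = NetworkState()
    cont.add_items(ABCDE)
    event = cont.copy()

    # continuous path: integrate every second of the hour
    run_training_trial(cont, ABCDE, params, gates)
    SegmentRun(cont, params, gates).run(1800.0 - cont.clock)
    res_c = run_recall_test(cont, "A", ABCDE, params, gates)
    SegmentRun(cont, params, gates).run(3600.0 - cont.clock)

    # event-driven path: settle 10 s, then closed-form skip
    run_training_trial(event, ABCDE, params, gates)
    SegmentRun(event, params, gates).run(params.settle_duration)
    fast_forward(event, 1800.0 - event.clock, params)
    res_e = run_recall_test(event, "A", ABCDE, params, gates)
    SegmentRun(event, params, gates).run(params.settle_duration)
    fast_forward(event, 3600.0 - event.clock, params)

    assert res_e.accuracy == res_c.accuracy
    for attr in ("ctx", "hc"):
        W_c = getattr(cont, attr).W
        W_e = getattr(event, attr).W
        np.testing.assert_allclose(W_e, W_c, rtol=1e-4, atol=1e-9)


class TestTimelines:
    def test_epochs_sorted_and_train_test_sleep_present(self):
        spec = load_preset("baseline")
        epochs = build_epochs(spec)
        starts = [e.start_time for e in epochs]
        assert starts == sorted(starts)
        kinds = {e.kind for e in epochs}
        assert kinds == {"train_trial", "recall_test", "sleep_block"}
        assert sum(e.kind == "sleep_block" for e in epochs) == 4
        assert sum(e.kind == "train_trial" for e in epochs) == 10

    def test_overlapping_epochs_rejected(self, params):
        # two tests forced into the same morning slot cannot overlap, but a
        # sleep block colliding with late training must be caught
        spec = ExperimentSpec(
            name="bad", seed=1,
            days=(DaySpec(train=(TrainBlock(ABCDE, 1200),)),),
            nights=1)
        with pytest.raises(InvalidSpecificationError):
            build_epochs(spec)

    def test_nights_cannot_exceed_days(self):
        with pytest.raises(InvalidSpecificationError):
            ExperimentSpec(name="bad", seed=1, days=(DaySpec(),), nights=2)


class TestDeterminism:
    def test_same_seed_bit_identical_results(self):
        spec = ExperimentSpec(
            name="tiny", seed=99,
            days=(DaySpec(train=(TrainBlock(ABCDE, 2),),
                          tests=(TestSpec("A", ABCDE),)),
                  DaySpec(tests=(TestSpec("A", ABCDE),))),
            nights=1, trace_weights=False)
        b1 = run_experiment(spec)
        b2 = run_experiment(spec)
        pd.testing.assert_frame_equal(b1.recalls_frame(), b2.recalls_frame())
        pd.testing.assert_frame_equal(b1.replays_frame(), b2.replays_frame())
        np.testing.assert_array_equal(b1.final_state.ctx.W,
                                      b2.final_state.ctx.W)
        assert b1.final_state.clock == b2.final_state.clock

    def test_different_seeds_change_replay_cues(self):
        days = (DaySpec(train=(TrainBlock(ABCDE, 2),)),)
        cues = []
        for seed in (1, 2):
            spec = ExperimentSpec(name="tiny", seed=seed, days=days,
                                  nights=1, trace_weights=False)
            bundle = run_experiment(spec)
            cues.append(tuple(r.cue_item for r in bundle.replays))
        assert cues[0] != cues[1]
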