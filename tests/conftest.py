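"""Shared fixtures: default parameters and expensive simulation runs that
several tests inspect (session-scoped so each experiment runs once)."""

import numpy as np
import pytest

from seqreplay import (ModelParams, NetworkState, PlasticityGates,
                       load_preset, run_experiment)
from seqreplay.engine import SegmentRun
from seqreplay.protocol import fast_forward, run_training_trial

ABCDE = tuple("ABCDE")
FORWARD = list(zip(ABCDE, ABCDE[1:]))


@pytest.fixture(scope="session")
def params():
    return ModelParams()


def train_day(net: NetworkState, params: ModelParams, sequence=ABCDE,
              trials: int = 10, gates: PlasticityGates | None = None):
    """Day-1 style training: trials at the published timings (2 s items,
    5 ms ISI, 1 min between trials, with post-trial settling)."""
    gates = gates or PlasticityGates()
    for _ in range(trials):
        run_training_trial(net, sequence, params, gates)
        SegmentRun(net, params, gates).run(params.settle_duration)
        fast_forward(net, params.inter_trial_gap - params.settle_duration,
                     params)
    return net


@pytest.fixture(scope="session")
def day1_network(params):
    """Network after ten Day-1 training trials of ABCDE (read-only)."""
    net = NetworkState()
    train_day(net, params)
    return net


def mean_forward(region, net, pairs=FORWARD):
    cat = net.catalog
    return float(np.mean([region.W[cat.index(a), cat.index(b)]
                          for a, b in pairs]))


@pytest.fixture(scope="session")
def preset_bundles():
    """One run of every packaged preset at its shipped seed."""
    out = {}
    for name in ("baseline", "lesion", "salience_two_seq", "competition",
                 "hc_sleep_off", "overlap"):
        out[name] = run_experiment(load_preset(name))
    return out
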