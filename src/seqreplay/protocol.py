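"""Declarative experiment timelines and the event-driven runner.

An experiment is a sequence of days; each day may hold training trials
(sequences presented to the input register), recall tests, and a night-time
block of slow-wave sleep.  Idle stretches between events are fast-forwarded
analytically (transients reset; weights and salience decayed in closed
form), after a short settle window of ordinary integration that lets the
activity left by the previous event die down the same way continuous
integration would.

Default clock layout (configurable): day ``d`` occupies
``[(d-1)*86400, d*86400)`` seconds; morning recall tests run at hour 8,
training starts at hour 9, a daytime test follows the last trial by 60 s,
and the SWS block starts at hour 23.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import SegmentRun
from .metrics import RecallResult, replay_statistics
from .params import ModelParams
from .plasticity import PlasticityGates, decay_weights_closed_form
from .replay import ReplayRecord, decay_salience_closed_form, run_sleep_block
from .state import NetworkState, reset_transients

__all__ = [
    "Epoch", "TrainBlock", "TestSpec", "DaySpec", "ExperimentSpec",
    "ResultBundle", "run_training_trial", "run_recall_test", "fast_forward",
    "run_experiment", "build_epochs",
]

DAY_SECONDS = 86400.0
MORNING_TEST_HOUR = 8.0
TRAINING_HOUR = 9.0
SLEEP_HOUR = 23.0


class InvalidSpecificationError(ValueError):
    """Raised for malformed or overlapping experiment timelines."""


# ----------------------------------------------------------------------
# Declarative specification types
@dataclass(frozen=True)
class TrainBlock:
    sequence: tuple[str, ...]
    trials: int

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise InvalidSpecificationError("training sequence must be non-empty")
        if self.trials < 0:
            raise InvalidSpecificationError("trial count must be >= 0")


@dataclass(frozen=True)
class TestSpec:
    __test__ = False       # not a pytest collectable

    cue: str
    target: tuple[str, ...]
    when: str = "auto"     # "morning" | "after_training" | "auto"


@dataclass(frozen=True)
class DaySpec:
    train: tuple[TrainBlock, ...] = ()
    tests: tuple[TestSpec, ...] = ()


@dataclass
class ExperimentSpec:
    name: str
    seed: int
    days: tuple[DaySpec, ...]
    nights: int
    params: ModelParams = field(default_factory=ModelParams)
    gates: PlasticityGates = field(default_factory=PlasticityGates)
    hc_to_ctx_enabled: bool = True
    trace_weights: bool = True     # sample tracked-link weights at >= 10 Hz
    trace_interval: float = 0.1

    def __post_init__(self):
        if self.seed is None:
            raise InvalidSpecificationError("an RNG seed is required")
        if self.nights < 0 or self.nights > len(self.days):
            raise InvalidSpecificationError(
                "nights must lie between 0 and the number of days")

    def sequences(self) -> dict[str, tuple[str, ...]]:
        """All distinct training sequences, keyed by their joined labels."""
        out: dict[str, tuple[str, ...]] = {}
        for day in self.days:
            for block in day.train:
                out.setdefault("".join(block.sequence), block.sequence)
        return out


@dataclass(frozen=True)
class Epoch:
    kind: str            # train_trial | recall_test | sleep_block
    start_time: float
    duration: float      # worst-case duration, for overlap checking
    sequence: tuple[str, ...] = ()
    cue: str | None = None
    target: tuple[str, ...] = ()
    night_index: int = 0
    day: int = 0


def trial_duration(sequence: Sequence[str], params: ModelParams) -> float:
    k = len(sequence)
    return k * params.train_item_duration + (k - 1) * params.inter_stimulus_interval


def build_epochs(spec: ExperimentSpec) -> list[Epoch]:
    """Expand the day-level shorthand into a sorted, non-overlapping timeline."""
    p = spec.params
    epochs: list[Epoch] = []
    for d, day in enumerate(spec.days, start=1):
        base = (d - 1) * DAY_SECONDS
        has_training = any(b.trials > 0 for b in day.train)

        t = base + MORNING_TEST_HOUR * 3600.0
        for test in day.tests:
            when = test.when
            if when == "auto":
                when = "after_training" if has_training else "morning"
            if when == "morning":
                epochs.append(Epoch("recall_test", t, p.recall_ceiling,
                                    cue=test.cue, target=test.target, day=d))
                t += p.recall_ceiling + 60.0

        t = base + TRAINING_HOUR * 3600.0
        for block in day.train:
            dur = trial_duration(block.sequence, p)
            for _ in range(block.trials):
                epochs.append(Epoch("train_trial", t, dur,
                                    sequence=block.sequence, day=d))
                t += dur + p.inter_trial_gap
        last_training_end = t - p.inter_trial_gap + 60.0 if has_training else t
        for test in day.tests:
            when = test.when
            if when == "auto":
                when = "after_training" if has_training else "morning"
            if when == "after_training":
                epochs.append(Epoch("recall_test", last_training_end,
                                    p.recall_ceiling, cue=test.cue,
                                    target=test.target, day=d))
                last_training_end += p.recall_ceiling + 60.0

        if d <= spec.nights:
            block_dur = spec.params.up_states_per_night / p.swo_frequency
            epochs.append(Epoch("sleep_block", base + SLEEP_HOUR * 3600.0,
                                block_dur, night_index=d, day=d))

    epochs.sort(key=lambda e: e.start_time)
    for prev, nxt in zip(epochs, epochs[1:]):
        if prev.start_time + prev.duration > nxt.start_time + 1e-9:
            raise InvalidSpecificationError(
                f"overlapping epochs at t={prev.start_time:.1f}s "
                f"({prev.kind}) and t={nxt.start_time:.1f}s ({nxt.kind})")
    return epochs


# ----------------------------------------------------------------------
# Primitive operations
def run_training_trial(state: NetworkState, sequence: Sequence[str],
                       params: ModelParams,
                       gates: PlasticityGates | None = None,
                       on_chunk=None, chunk_steps: int | None = None,
                       ) -> NetworkState:
    """Present a sequence once: each item 2 s at level 0.1, 5 ms apart.

    Novel labels are allocated before presentation; dynamics, link
    instantiation, plasticity and salience all update every step.
    """
    if len(sequence) == 0:
        raise ValueError("training sequence must be non-empty")
    state.mode = "wake"
    state.add_items(sequence)
    run = SegmentRun(state, params, gates)
    for i, item in enumerate(sequence):
        run.run(params.train_item_duration, drive_label=item,
                drive_amp=params.train_input_level, allow_links=True,
                on_chunk=on_chunk, chunk_steps=chunk_steps)
        if i + 1 < len(sequence):
            run.run(params.inter_stimulus_interval, allow_links=True,
                    on_chunk=on_chunk, chunk_steps=chunk_steps)
    return state


def run_recall_test(state: NetworkState, cue: str, target: Sequence[str],
                    params: ModelParams,
                    gates: PlasticityGates | None = None,
                    sever_hc_feedback: bool = False,
                    on_chunk=None, chunk_steps: int | None = None,
                    **meta) -> RecallResult:
    """Cue a recall (0.1 for 1.5 s) and watch the cortical cascade.

    Integration continues past the cue until every target item has crossed
    the recall threshold or the 30 s ceiling elapses.  Learning and salience
    stay active (a recall strengthens existing links); no new links form.
    ``sever_hc_feedback`` temporarily disables hippocampal feedback for this
    test only.
    """
    if cue not in state.catalog:
        raise ValueError(f"unknown recall cue {cue!r}")
    state.mode = "wake"
    restore = state.hc_to_ctx_enabled
    if sever_hc_feedback:
        state.hc_to_ctx_enabled = False
    try:
        run = SegmentRun(state, params, gates, stop_labels=target)
        run.run(params.recall_cue_duration, drive_label=cue,
                drive_amp=params.recall_cue_level,
                on_chunk=on_chunk, chunk_steps=chunk_steps)
        if not run.completed:
            run.run(params.recall_ceiling - run.elapsed,
                    on_chunk=on_chunk, chunk_steps=chunk_steps)
    finally:
        state.hc_to_ctx_enabled = restore
    return RecallResult.from_crossings(
        cue, tuple(target), run.crossings_ctx,
        ceiling=params.recall_ceiling, **meta)


def fast_forward(state: NetworkState, elapsed: float,
                 params: ModelParams) -> NetworkState:
    """Skip an idle interval analytically.

    Transients are zeroed; weights and salience follow their exact
    decay-only solutions; the clock advances.
    """
    if elapsed < 0:
        raise ValueError("elapsed time must be non-negative")
    reset_transients(state)
    decay_weights_closed_form(state.ctx, elapsed, params)
    decay_weights_closed_form(state.hc, elapsed, params)
    decay_salience_closed_form(state, elapsed, params)
    state.advance_clock(elapsed)
    return state


# ----------------------------------------------------------------------
# Results
@dataclass
class ResultBundle:
    spec: ExperimentSpec
    recalls: list[RecallResult]
    replays: list[ReplayRecord]
    weights: pd.DataFrame            # time, region, pre, post, weight
    salience: pd.DataFrame           # time, item, salience
    summary: dict
    final_state: NetworkState

    def recalls_frame(self) -> pd.DataFrame:
        rows = [{
            "day": r.day, "time_s": r.time, "cue": r.cue,
            "target": "".join(r.target),
            "crossing_order": "".join(c for c, _ in r.crossings),
            "accuracy_pct": r.accuracy, "recall_time_s": r.recall_time,
        } for r in self.recalls]
        return pd.DataFrame(rows, columns=["day", "time_s", "cue", "target",
                                           "crossing_order", "accuracy_pct",
                                           "recall_time_s"])

    def replays_frame(self) -> pd.DataFrame:
        rows = [{
            "night": r.night_index, "up_index": r.up_index,
            "cue": r.cue_item if r.cue_item is not None else "NULL",
            "crossing_items": "".join(c for c, _ in r.crossings),
            "crossing_times": ";".join(f"{t:.9g}" for _, t in r.crossings),
            "attributed_sequence": r.attributed_sequence or "",
            "full_replay": r.full_replay,
            "duration_s": "" if r.duration is None else f"{r.duration:.9g}",
        } for r in self.replays]
        return pd.DataFrame(rows, columns=["night", "up_index", "cue",
                                           "crossing_items", "crossing_times",
                                           "attributed_sequence",
                                           "full_replay", "duration_s"])


# ----------------------------------------------------------------------
class _WeightTracer:
    """Samples tracked-link weights (long format) during events."""

    def __init__(self, spec: ExperimentSpec) -> None:
        self.enabled = spec.trace_weights
        self.interval = spec.trace_interval
        self.pairs: list[tuple[str, str]] = []
        seen = set()
        for seq in spec.sequences().values():
            for pre, post in zip(seq, seq[1:]):
                if (pre, post) not in seen:
                    seen.add((pre, post))
                    self.pairs.append((pre, post))
        self.rows: list[tuple] = []

    def chunk_steps(self, params: ModelParams) -> int | None:
        if not self.enabled:
            return None
        return max(1, int(round(self.interval / params.dt)))

    def sample(self, state: NetworkState) -> None:
        if not self.enabled:
            return
        cat = state.catalog
        for region in (state.ctx, state.hc):
            for pre, post in self.pairs:
                if pre in cat and post in cat:
                    i, j = cat.index(pre), cat.index(post)
                    self.rows.append((state.clock, region.region, pre, post,
                                      region.W[i, j]))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["time_s", "region", "pre",
                                                "post", "weight"])


def run_experiment(spec: ExperimentSpec) -> ResultBundle:
    """Execute a full experiment timeline, reproducibly for a given seed."""
    params = spec.params
    gates = spec.gates
    rng = np.random.default_rng(spec.seed)
    state = NetworkState()
    state.hc_to_ctx_enabled = spec.hc_to_ctx_enabled
    epochs = build_epochs(spec)
    sequences = spec.sequences()

    tracer = _WeightTracer(spec)
    chunk = tracer.chunk_steps(params)
    on_chunk = tracer.sample if tracer.enabled else None

    recalls: list[RecallResult] = []
    replays: list[ReplayRecord] = []
    salience_rows: list[tuple] = []

    for epoch in epochs:
        gap = epoch.start_time - state.clock
        if gap < -1e-9:
            raise InvalidSpecificationError(
                f"epoch at t={epoch.start_time:.1f}s starts before the clock "
                f"({state.clock:.1f}s); epochs overlap")
        _advance_to(state, epoch.start_time, params, gates)

        if epoch.kind == "train_trial":
            run_training_trial(state, epoch.sequence, params, gates,
                               on_chunk=on_chunk, chunk_steps=chunk)
        elif epoch.kind == "recall_test":
            res = run_recall_test(state, epoch.cue, epoch.target, params,
                                  gates, day=epoch.day, time=epoch.start_time,
                                  on_chunk=on_chunk, chunk_steps=chunk)
            recalls.append(res)
        elif epoch.kind == "sleep_block":
            state, recs = run_sleep_block(state, params, epoch.night_index,
                                          rng, gates, sequences,
                                          on_chunk=on_chunk, chunk_steps=chunk)
            replays.extend(recs)
            tracer.sample(state)
        else:  # pragma: no cover - guarded by Epoch construction
            raise InvalidSpecificationError(f"unknown epoch kind {epoch.kind!r}")

        for lab in state.catalog:
            salience_rows.append((state.clock, lab,
                                  state.salience[state.catalog.index(lab)]))

    summary = {
        "name": spec.name,
        "seed": spec.seed,
        "n_items": state.n,
        "recalls": [{"day": r.day, "cue": r.cue, "accuracy_pct": r.accuracy,
                     "recall_time_s": r.recall_time} for r in recalls],
        "replay_nights": {
            str(k): v for k, v in replay_statistics(replays, sequences).items()
        },
    }
    return ResultBundle(
        spec=spec, recalls=recalls, replays=replays,
        weights=tracer.frame(),
        salience=pd.DataFrame(salience_rows,
                              columns=["time_s", "item", "salience"]),
        summary=summary, final_state=state,
    )


def _advance_to(state: NetworkState, target_time: float, params: ModelParams,
                gates: PlasticityGates) -> None:
    """Settle residual activity by integration, then fast-forward the rest."""
    gap = target_time - state.clock
    if gap <= 0:
        return
    state.mode = "wake"
    residual = 0.0
    if state.n:
        residual = max(state.ctx.a.max(initial=0.0), state.hc.a.max(initial=0.0),
                       state.ctx.g.max(initial=0.0), state.hc.g.max(initial=0.0))
    settle = min(gap, params.settle_duration) if residual > 1e-12 else 0.0
    if settle > 0:
        SegmentRun(state, params, gates).run(settle)
    fast_forward(state, max(0.0, target_time - state.clock), params)
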