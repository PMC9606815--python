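"""Salience dynamics and slow-wave-sleep replay generation.

Each item carries a salience trace, a leaky moving average of its waking
cortical activation:

    ds_x/dt = -s_x / tau_s + lambda * a_x      (lambda = 0 during sleep)

A night of slow-wave sleep is a block of 1 Hz slow oscillations; each UP
state samples one item (or a fixed-salience null outcome) with probability
proportional to salience, pulses the chosen item's input-register entry
briefly, and lets activity spread through the learned links at the fast
sleep timescale — a time-compressed replay.  Activations and inactivation
currents are reset at every UP-state boundary; sleep activity never feeds
back into salience.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .engine import SegmentRun, steps_for
from .params import ModelParams
from .plasticity import PlasticityGates, decay_weights_closed_form
from .state import NetworkState, reset_transients

__all__ = [
    "ReplayRecord",
    "update_salience",
    "decay_salience_closed_form",
    "sample_replay_cue",
    "run_sleep_block",
]


@dataclass
class ReplayRecord:
    """Outcome of one UP state: its cue and the cortical crossings it evoked."""

    night_index: int
    up_index: int
    cue_item: str | None                        # None = null item (no replay)
    crossings: tuple[tuple[str, float], ...]    # (item, s within the UP state)
    crossings_hc: tuple[tuple[str, float], ...] = ()
    attributed_sequence: str | None = None
    full_replay: bool = False
    duration: float | None = None               # defined only for full replays


def update_salience(state: NetworkState, params: ModelParams,
                    dt: float | None = None) -> NetworkState:
    """One Euler step of the salience trace from cortical activations."""
    if dt is None:
        dt = params.dt
    lam = params.lambda_(state.mode)
    s = state.salience
    s += dt * (-s / params.tau_s + lam * state.ctx.a)
    np.maximum(s, 0.0, out=s)
    return state


def decay_salience_closed_form(state: NetworkState, elapsed: float,
                               params: ModelParams) -> NetworkState:
    """Exact salience decay over an idle interval: s *= exp(-t/tau_s)."""
    if elapsed < 0:
        raise ValueError("elapsed time must be non-negative")
    state.salience *= np.exp(-elapsed / params.tau_s)
    return state


def sample_replay_cue(salience: np.ndarray, null_salience: float,
                      rng: np.random.Generator) -> int | None:
    """Draw one item index (or None for the null item) proportionally to salience.

    Consumes exactly one uniform draw from ``rng``.
    """
    salience = np.asarray(salience, dtype=float)
    if np.any(salience < 0) or null_salience < 0:
        raise ValueError("saliences must be non-negative")
    total = salience.sum() + null_salience
    if total <= 0:
        raise ValueError(
            "cannot sample a cue: all saliences and the null salience are zero")
    u = rng.random() * total
    acc = 0.0
    for i, s in enumerate(salience):
        acc += s
        if u < acc:
            return i
    return None


def run_sleep_block(state: NetworkState, params: ModelParams,
                    night_index: int, rng: np.random.Generator,
                    gates: PlasticityGates | None = None,
                    sequences: Mapping[str, Sequence[str]] | None = None,
                    on_chunk=None, chunk_steps: int | None = None,
                    ) -> tuple[NetworkState, list[ReplayRecord]]:
    """Simulate one night of SWS: a block of UP/DOWN cycles with cued replays.

    Per UP state: sample a cue from the salience distribution (plus the null
    item); if non-null, pulse that cortical item's input-register entry
    (amplitude 0.2, 12.5 ms) at UP-state onset; integrate the sleep-speed
    dynamics with plasticity for the UP-state duration; reset transients.
    The DOWN half of each cycle is idle and handled in closed form (weight
    decay only).  Salience is untouched by sleep activity and decays in
    closed form over the whole block.
    """
    gates = gates or PlasticityGates()
    state.mode = "sleep"
    cycle = 1.0 / params.swo_frequency
    down_duration = max(0.0, cycle - params.up_state_duration)
    pulse_steps = steps_for(params.sleep_cue_duration, params.dt)
    up_steps = steps_for(params.up_state_duration, params.dt)
    block_start = state.clock
    records: list[ReplayRecord] = []

    for up in range(params.up_states_per_night):
        cue_idx = sample_replay_cue(state.salience, params.null_salience, rng)
        cue_label = None if cue_idx is None else state.catalog.label(cue_idx)

        run = SegmentRun(state, params, gates)
        if cue_label is not None and state.n > 0:
            run.run(pulse_steps * params.dt, drive_label=cue_label,
                    drive_amp=params.sleep_cue_amplitude,
                    on_chunk=on_chunk, chunk_steps=chunk_steps)
            run.run((up_steps - pulse_steps) * params.dt,
                    on_chunk=on_chunk, chunk_steps=chunk_steps)
        elif state.n > 0:
            run.run(up_steps * params.dt,
                    on_chunk=on_chunk, chunk_steps=chunk_steps)
        else:
            state.advance_clock(up_steps * params.dt)

        rec = _make_record(night_index, up, cue_label, run, sequences)
        records.append(rec)

        reset_transients(state)
        decay_weights_closed_form(state.ctx, down_duration, params)
        decay_weights_closed_form(state.hc, down_duration, params)
        state.advance_clock(down_duration)

    # Sleep activity never feeds salience; exact decay over the whole block.
    decay_salience_closed_form(state, state.clock - block_start, params)
    state.mode = "wake"
    return state, records


def _make_record(night_index: int, up: int, cue_label: str | None,
                 run: SegmentRun,
                 sequences: Mapping[str, Sequence[str]] | None) -> ReplayRecord:
    attributed = None
    full = False
    duration = None
    if cue_label is not None and sequences:
        for name, items in sequences.items():
            if cue_label in items:
                attributed = name
                crossed = {c for c, _ in run.crossings_ctx}
                if set(items) <= crossed:
                    full = True
                    times = {}
                    for c, t in run.crossings_ctx:
                        if c in items and c not in times:
                            times[c] = t
                    duration = max(times.values()) - min(times.values())
                break
    return ReplayRecord(
        night_index=night_index,
        up_index=up,
        cue_item=cue_label,
        crossings=tuple(run.crossings_ctx),
        crossings_hc=tuple(run.crossings_hc),
        attributed_sequence=attributed,
        full_replay=full,
        duration=duration,
    )
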