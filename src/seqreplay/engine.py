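"""Driver that feeds :class:`~seqreplay.state.NetworkState` through the
compiled kernel in chunks, accumulating threshold crossings across the
constant-drive segments that make up one continuous stretch of integration
(a training presentation, a recall test, an UP state...).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

from ._kernel import run_segment
from .dynamics import NumericalInstabilityError
from .params import ModelParams, pack_params
from .plasticity import PlasticityGates
from .state import NetworkState

__all__ = ["SegmentRun", "steps_for"]


def steps_for(duration: float, dt: float) -> int:
    """Number of Euler steps covering ``duration`` (rounded to the grid)."""
    return max(0, int(round(duration / dt)))


class SegmentRun:
    """One continuous integration window with crossing bookkeeping.

    Crossing times are seconds since the window opened (= cue onset for a
    recall test, UP-state onset for a replay).  ``stop_labels`` defines an
    optional early-stop set: integration halts once every item in the set
    has crossed the cortical recall threshold.
    """

    def __init__(self, net: NetworkState, params: ModelParams,
                 gates: PlasticityGates | None = None,
                 stop_labels: Iterable[str] | None = None) -> None:
        self.net = net
        self.params = params
        self.gates = gates or PlasticityGates()
        self.crossings_ctx: list[tuple[str, float]] = []
        self.crossings_hc: list[tuple[str, float]] = []
        self._step = 0          # steps elapsed since window start
        self._crossed_stop = np.full(net.n, -1, dtype=np.int8)
        self._stop_on = False
        if stop_labels is not None:
            for lab in stop_labels:
                self._crossed_stop[net.catalog.index(lab)] = 0
            self._stop_on = True

    # ------------------------------------------------------------------
    @property
    def elapsed(self) -> float:
        return self._step * self.params.dt

    @property
    def completed(self) -> bool:
        """True when every stop-set item has crossed threshold."""
        return self._stop_on and not np.any(self._crossed_stop == 0)

    # ------------------------------------------------------------------
    def run(self, duration: float, drive_label: str | None = None,
            drive_amp: float = 0.0, allow_links: bool = False,
            chunk_steps: int | None = None,
            on_chunk: Callable[[NetworkState], None] | None = None) -> int:
        """Integrate up to ``duration`` under a constant drive.

        Returns the number of steps actually integrated (fewer than
        requested if the stop set completed).
        """
        net, params = self.net, self.params
        n_steps = steps_for(duration, params.dt)
        if n_steps == 0 or net.n == 0:
            net.advance_clock(n_steps * params.dt)
            return n_steps
        p = pack_params(params, net.mode)
        wake = net.mode == "wake"
        learn_c = net.ctx.learning_enabled and self.gates.enabled("CTX", net.mode)
        learn_h = net.hc.learning_enabled and self.gates.enabled("HC", net.mode)
        drive_index = -1 if drive_label is None else net.catalog.index(drive_label)

        cap = 16 * net.n + 64
        ci_c = np.empty(cap, dtype=np.int64)
        ct_c = np.empty(cap, dtype=np.int64)
        ci_h = np.empty(cap, dtype=np.int64)
        ct_h = np.empty(cap, dtype=np.int64)

        chunk = n_steps if chunk_steps is None else max(1, chunk_steps)
        done_total = 0
        while done_total < n_steps:
            todo = min(chunk, n_steps - done_total)
            ncc, nch, done = run_segment(
                net.ctx.a, net.ctx.g, net.hc.a, net.hc.g,
                net.ctx.W, net.hc.W, net.ctx.exists, net.hc.exists,
                net.salience,
                drive_index, drive_amp, todo, p,
                learn_c, learn_h, allow_links, net.hc_to_ctx_enabled, wake,
                ci_c, ct_c, ci_h, ct_h, 0, 0,
                self._crossed_stop, self._stop_on, self._step,
            )
            for buf_i, buf_t, out in ((ci_c, ct_c, self.crossings_ctx),
                                      (ci_h, ct_h, self.crossings_hc)):
                count = ncc if out is self.crossings_ctx else nch
                for k in range(count):
                    out.append((net.catalog.label(int(buf_i[k])),
                                (buf_t[k] + 1) * params.dt))
            self._step += done
            done_total += done
            net.advance_clock(done * params.dt)
            self._check_finite()
            if on_chunk is not None:
                on_chunk(net)
            if self._stop_on and self.completed:
                break
        return done_total

    # ------------------------------------------------------------------
    def _check_finite(self) -> None:
        net = self.net
        for region in (net.ctx, net.hc):
            bad = ~np.isfinite(region.a) | ~np.isfinite(region.g)
            if bad.any():
                label = net.catalog.label(int(np.flatnonzero(bad)[0]))
                raise NumericalInstabilityError(
                    f"non-finite state for item {label!r} in {region.region}")
            if not np.all(np.isfinite(region.W)):
                raise NumericalInstabilityError(
                    f"non-finite weights in {region.region}")
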