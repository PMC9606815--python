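"""Link instantiation and the causal rate-based learning rule.

The weight of a directed link x -> y evolves as

    dw_xy/dt = -w_xy / tau_eff
               + eta * a_x * (1 - w_xy) * ([da_y/dt]+ - Q * [-da_y/dt]+)

so a presynaptic item that is active while the postsynaptic activation is
rising potentiates the link, while a falling postsynaptic activation
depresses it by the fraction Q.  At Q = 0.5 reverse links between
sequentially experienced items are eliminated while forward links grow.
Passive decay runs at all times; the Hebbian/depression terms are gated by
the region's learning switch.  Links are created (at weight 0, in both
directions) at the first co-activation of two items, but only during wake
training presentations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import NumericalInstabilityError
from .params import ModelParams
from .state import NetworkState, RegionState

__all__ = [
    "PlasticityGates",
    "instantiate_links",
    "update_weights",
    "decay_weights_closed_form",
]


@dataclass
class PlasticityGates:
    """Per-region, per-mode switches for the Hebbian/depression terms.

    Passive weight decay is not gated: it models spontaneous synaptic
    turnover and runs whether or not learning is enabled.
    """

    hc_learning_wake: bool = True
    hc_learning_sleep: bool = True
    ctx_learning_wake: bool = True
    ctx_learning_sleep: bool = True

    def enabled(self, region: str, mode: str) -> bool:
        key = f"{'hc' if region == 'HC' else 'ctx'}_learning_{mode}"
        return getattr(self, key)


def instantiate_links(state: NetworkState, params: ModelParams,
                      external_training_active: bool = True) -> NetworkState:
    """Create links between co-active items, independently per region.

    For every ordered pair (x, y) whose activations both exceed the
    co-activation threshold and that is not yet linked, links are created in
    both directions at weight 0.  Only has an effect while an external
    training presentation is active (new connections cannot be created
    during recall or sleep).
    """
    if not external_training_active:
        return state
    for region in (state.ctx, state.hc):
        active = region.a > params.coactivation_threshold
        idx = np.flatnonzero(active)
        if idx.size >= 2:
            pair = np.ix_(idx, idx)
            newly = ~region.exists[pair]
            region.exists[pair] |= newly
            np.fill_diagonal(region.exists, False)
    return state


def update_weights(region: RegionState, a: np.ndarray, dadt: np.ndarray,
                   params: ModelParams, dt: float | None = None,
                   learning_on: bool = True) -> RegionState:
    """One Euler step of the learning rule on all existing links, in place.

    ``a`` and ``dadt`` are the activation snapshot and analytic derivative
    from the same (pre-update) state the dynamics step used.
    """
    if dt is None:
        dt = params.dt
    a = np.asarray(a, dtype=float)
    dadt = np.asarray(dadt, dtype=float)
    if a.shape != (region.n,) or dadt.shape != (region.n,):
        raise ValueError("activation/derivative shape does not match region")
    eta = params.eta_h if region.region == "HC" else params.eta_c
    decay_rate = params.weight_decay_rate(region.region)

    W = region.W
    dW = -W * decay_rate
    if learning_on:
        bracket = np.where(dadt > 0.0, dadt, params.Q * dadt)
        dW = dW + eta * a[:, None] * (1.0 - W) * bracket[None, :]
    if not np.all(np.isfinite(dW)):
        raise NumericalInstabilityError(
            f"non-finite weight update in {region.region}")
    W += dt * dW
    np.clip(W, 0.0, 1.0, out=W)
    W[~region.exists] = 0.0
    return region


def decay_weights_closed_form(region: RegionState, elapsed: float,
                              params: ModelParams) -> RegionState:
    """Exact decay-only solution over an idle interval: w *= exp(-t/tau_eff)."""
    if elapsed < 0:
        raise ValueError("elapsed time must be non-negative")
    region.W *= np.exp(-elapsed * params.weight_decay_rate(region.region))
    return region
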