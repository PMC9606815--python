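"""Item-level shunting dynamics of the two memory regions.

Activation of item ``x`` obeys

    sigma_a * da_x/dt = -a_x / tau_a + (1 - a_x) * E_x - a_x * I_x

where ``E_x`` sums feedforward drive, spreading excitation through learned
links and a sigmoidal self-excitation, and ``I_x`` sums lateral inhibition
from all other items plus a sigmoidal function of a slow inactivation
current ``g_x`` that terminates prolonged activations:

    sigma_g * dg_x/dt = -g_x / tau_g + (1 - g_x) * kappa * a_x

The functions here are the reference (pure numpy) implementation used by
tests and single-step inspection; long simulations go through the compiled
kernel in :mod:`seqreplay._kernel`, which a test pins to these semantics.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams
from .state import NetworkState, RegionState

__all__ = [
    "excitatory_input",
    "inhibitory_input",
    "step_network",
    "NumericalInstabilityError",
]


class NumericalInstabilityError(RuntimeError):
    """Raised when integration produces a non-finite state."""


def _check_shape(vec: np.ndarray, n: int, name: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n,):
        raise ValueError(f"{name} has shape {vec.shape}, expected ({n},)")
    return vec


def excitatory_input(region: RegionState, feedforward: np.ndarray,
                     feedback: np.ndarray, params: ModelParams) -> np.ndarray:
    """Net excitatory input E to every item of a region.

    ``feedforward`` is the input-register drive for the cortex and the
    cortical activation vector for the hippocampus; ``feedback`` is the
    rectified hippocampal activation scaled by zeta for the cortex (zero
    for the hippocampus, or when the feedback pathway is lesioned).
    """
    n = region.n
    F = _check_shape(feedforward, n, "feedforward")
    fb = _check_shape(feedback, n, "feedback")
    mu = params.mu_c if region.region == "CTX" else params.mu_h
    a = region.a
    spread = region.W.T @ a                      # sum_y w_yx * a_y (diag is 0)
    am = a ** params.m
    self_exc = params.alpha * am / (am + params.t_a ** params.m)
    return mu * F + params.gamma * spread + self_exc + fb


def inhibitory_input(region: RegionState, params: ModelParams) -> np.ndarray:
    """Net inhibitory input I: lateral inhibition plus delayed self-inhibition."""
    a, g = region.a, region.g
    lateral = params.beta * (a.sum() - a)
    gn = g ** params.n
    inact = params.theta * gn / (gn + params.t_h ** params.n)
    return lateral + inact


def _region_derivatives(region: RegionState, E: np.ndarray, I: np.ndarray,
                        params: ModelParams, sigma_a: float, sigma_g: float):
    dadt = (-region.a / params.tau_a + (1.0 - region.a) * E - region.a * I) / sigma_a
    dgdt = (-region.g / params.tau_g
            + (1.0 - region.g) * params.kappa * region.a) / sigma_g
    return dadt, dgdt


def step_network(state: NetworkState, input_register: np.ndarray,
                 params: ModelParams, dt: float | None = None):
    """One synchronous forward-Euler step of both regions, in place.

    The hippocampus is fed by the previous-step cortical activation; the
    cortex receives the rectified previous-step hippocampal feedback (unless
    lesioned).  Returns the analytic derivatives ``(dadt_ctx, dadt_hc)``
    evaluated at the pre-update state — these drive the learning rule.
    """
    if dt is None:
        dt = params.dt
    n = state.n
    F_ctx = _check_shape(input_register, n, "input_register")
    sigma_a = params.sigma_a(state.mode)
    sigma_g = params.sigma_g_(state.mode)

    if state.hc_to_ctx_enabled:
        fb = params.zeta * np.maximum(state.hc.a, 0.0)
    else:
        fb = np.zeros(n)
    zero = np.zeros(n)

    E_c = excitatory_input(state.ctx, F_ctx, fb, params)
    I_c = inhibitory_input(state.ctx, params)
    E_h = excitatory_input(state.hc, state.ctx.a, zero, params)
    I_h = inhibitory_input(state.hc, params)

    dadt_c, dgdt_c = _region_derivatives(state.ctx, E_c, I_c, params,
                                         sigma_a, sigma_g)
    dadt_h, dgdt_h = _region_derivatives(state.hc, E_h, I_h, params,
                                         sigma_a, sigma_g)

    for region, dadt, dgdt in ((state.ctx, dadt_c, dgdt_c),
                               (state.hc, dadt_h, dgdt_h)):
        region.a = np.clip(region.a + dt * dadt, 0.0, 1.0)
        region.g = np.clip(region.g + dt * dgdt, 0.0, 1.0)
        bad = ~np.isfinite(region.a) | ~np.isfinite(region.g)
        if bad.any():
            label = state.catalog.label(int(np.flatnonzero(bad)[0]))
            raise NumericalInstabilityError(
                f"non-finite state for item {label!r} in {region.region}"
            )
    state.advance_clock(dt)
    return state, dadt_c, dadt_h
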