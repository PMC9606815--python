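"""Model parameters for the cortico-hippocampal sequence-memory simulator.

All quantities are in seconds (durations, time constants) or are
dimensionless gains.  The defaults reproduce the published operating point
of the model: a fast-learning, fast-forgetting hippocampus coupled to a
slow-learning, slow-forgetting cortex, with shunting activation dynamics,
delayed self-inhibition, a causal rate-based learning rule, and a salience
trace that biases which item cues each slow-wave-sleep replay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np

__all__ = ["ModelParams", "pack_params", "NP"]


@dataclass
class ModelParams:
    # -- item activation (shunting dynamics) --------------------------------
    sigma_a_wake: float = 2.0      # speed-of-dynamics divisor, wake
    sigma_a_sleep: float = 0.04    # speed-of-dynamics divisor, sleep
    tau_a: float = 0.8             # activation passive-decay constant
    mu_h: float = 2.0              # feedforward gain, cortex -> hippocampus
    mu_c: float = 1.0              # feedforward gain, input register -> cortex
    gamma: float = 0.9             # spreading excitation along learned links
    alpha: float = 1.0             # self-excitation gain
    m: int = 2                     # self-excitation sigmoid order
    t_a: float = 0.09              # self-excitation sigmoid threshold
    zeta: float = 0.5              # hippocampus -> cortex feedback gain
    beta: float = 15.0             # lateral inhibition gain
    theta: float = 10.0            # inactivation-current inhibition gain
    n: int = 2                     # inactivation sigmoid order
    t_h: float = 0.02              # inactivation sigmoid threshold

    # -- inactivation current ------------------------------------------------
    sigma_g: float = 10.0          # inactivation speed divisor, wake
    # Sleep value of the inactivation speed divisor.  None (default) scales
    # sigma_g by the same sleep/wake ratio as sigma_a, so that replay
    # activations fall as much faster as they rise; set explicitly to pin it.
    sigma_g_sleep: float | None = None
    tau_g: float = 1.2             # inactivation passive-decay constant
    kappa: float = 1.0             # activation -> inactivation drive

    # -- adaptive weights ----------------------------------------------------
    # Printed decay constants; interpreted per `tau_w_unit` (see below).
    tau_w_h: float = 1.5552e9
    tau_w_c: float = 3.73248e10
    Q: float = 0.5                 # non-causal (depression) fraction
    eta_h: float = 15.0            # hippocampal learning rate
    eta_c: float = 1.5             # cortical learning rate
    # "ms": tau_w values above are milliseconds and are converted to seconds.
    tau_w_unit: Literal["ms", "s"] = "ms"
    # If True (default, the literal reading of the learning rule), passive
    # weight decay is scaled by eta, giving effective e-fold decay of ~1.2
    # days in the hippocampus and ~288 days in the cortex: the hippocampal
    # trace of an untouched sequence fades within days while the cortical
    # trace persists.  False drops eta from the decay term (~18/~432 days).
    decay_scaled_by_eta: bool = True

    # -- item salience -------------------------------------------------------
    tau_s: float = 86400.0         # salience decay constant (1 day)
    lambda_wake: float = 1000.0    # salience input gate, wake
    lambda_sleep: float = 0.0      # salience input gate, sleep
    null_salience: float = 0.5     # fixed salience of the "no replay" item

    # -- integration & protocol constants -----------------------------------
    dt: float = 0.001                  # Euler step (s)
    recall_threshold: float = 0.01     # cortical activation recall threshold
    recall_ceiling: float = 30.0       # max recall observation window (s)
    coactivation_threshold: float = 0.01  # link-instantiation activity level
    train_input_level: float = 0.1
    train_item_duration: float = 2.0
    inter_stimulus_interval: float = 0.005
    inter_trial_gap: float = 60.0
    recall_cue_level: float = 0.1
    recall_cue_duration: float = 1.5
    sleep_cue_amplitude: float = 0.2
    sleep_cue_duration: float = 0.0125
    swo_frequency: float = 1.0         # Hz; one UP/DOWN cycle per period
    up_state_duration: float = 0.5
    up_states_per_night: int = 50
    settle_duration: float = 10.0      # zero-input integration before a skip

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        positive = (
            "sigma_a_wake", "sigma_a_sleep", "tau_a", "mu_h", "mu_c",
            "alpha", "t_a", "beta", "theta", "t_h", "sigma_g", "tau_g",
            "kappa", "tau_w_h", "tau_w_c", "eta_h", "eta_c", "tau_s",
            "dt", "recall_ceiling", "train_input_level",
            "train_item_duration", "recall_cue_level", "recall_cue_duration",
            "sleep_cue_amplitude", "sleep_cue_duration", "swo_frequency",
            "up_state_duration",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        for name in ("gamma", "zeta", "lambda_wake", "lambda_sleep",
                     "null_salience", "inter_stimulus_interval",
                     "inter_trial_gap", "settle_duration",
                     "coactivation_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be non-negative")
        if not 0.0 <= self.Q <= 1.0:
            raise ValueError("Q must lie in [0, 1]")
        if not 0.0 < self.recall_threshold < 1.0:
            raise ValueError("recall_threshold must lie in (0, 1)")
        if self.m < 1 or self.n < 1:
            raise ValueError("sigmoid orders m, n must be >= 1")
        if self.up_states_per_night < 0:
            raise ValueError("up_states_per_night must be >= 0")
        if not self.dt < self.up_state_duration:
            raise ValueError("dt must be smaller than up_state_duration")
        if self.sigma_g_sleep is not None and not self.sigma_g_sleep > 0:
            raise ValueError("sigma_g_sleep must be strictly positive")
        if self.tau_w_unit not in ("ms", "s"):
            raise ValueError("tau_w_unit must be 'ms' or 's'")
        if not (self.eta_h > self.eta_c):
            raise ValueError("hippocampus must learn faster than cortex (eta_h > eta_c)")
        if not (self.tau_w_h_seconds() < self.tau_w_c_seconds()):
            raise ValueError("hippocampal weights must decay faster than cortical ones")

    # ------------------------------------------------------------------
    def tau_w_h_seconds(self) -> float:
        return self.tau_w_h * (1e-3 if self.tau_w_unit == "ms" else 1.0)

    def tau_w_c_seconds(self) -> float:
        return self.tau_w_c * (1e-3 if self.tau_w_unit == "ms" else 1.0)

    def weight_decay_rate(self, region: str) -> float:
        """Effective passive decay rate (1/s) of adaptive weights."""
        if region == "HC":
            tau, eta = self.tau_w_h_seconds(), self.eta_h
        elif region == "CTX":
            tau, eta = self.tau_w_c_seconds(), self.eta_c
        else:
            raise ValueError(f"unknown region {region!r}")
        return (eta / tau) if self.decay_scaled_by_eta else (1.0 / tau)

    def sigma_a(self, mode: str) -> float:
        return self.sigma_a_wake if mode == "wake" else self.sigma_a_sleep

    def sigma_g_(self, mode: str) -> float:
        if mode == "wake":
            return self.sigma_g
        if self.sigma_g_sleep is not None:
            return self.sigma_g_sleep
        return self.sigma_g * self.sigma_a_sleep / self.sigma_a_wake

    def lambda_(self, mode: str) -> float:
        return self.lambda_wake if mode == "wake" else self.lambda_sleep

    def override(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (validated)."""
        valid = {f.name for f in fields(self)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(
                f"unknown parameter(s) {sorted(unknown)}; valid names: {sorted(valid)}"
            )
        return replace(self, **kwargs)


# ----------------------------------------------------------------------
# Packed parameter vector consumed by the numba kernel.  Index constants
# are shared between the kernel and the reference stepper.
TAU_A, MU_H, MU_C, GAMMA, ALPHA, T_A, ZETA, BETA, THETA, T_H = range(10)
SIGMA_G, TAU_G, KAPPA, Q_IDX, ETA_H, ETA_C, DECAY_H, DECAY_C = range(10, 18)
TAU_S, LAM, DT_IDX, SIGMA_A, THR, COACT, M_ORD, N_ORD = range(18, 26)
NP = 26


def pack_params(p: ModelParams, mode: str) -> np.ndarray:
    """Flatten parameters into the float64 vector used by the kernel."""
    v = np.empty(NP, dtype=np.float64)
    v[TAU_A] = p.tau_a
    v[MU_H] = p.mu_h
    v[MU_C] = p.mu_c
    v[GAMMA] = p.gamma
    v[ALPHA] = p.alpha
    v[T_A] = p.t_a
    v[ZETA] = p.zeta
    v[BETA] = p.beta
    v[THETA] = p.theta
    v[T_H] = p.t_h
    v[SIGMA_G] = p.sigma_g_(mode)
    v[TAU_G] = p.tau_g
    v[KAPPA] = p.kappa
    v[Q_IDX] = p.Q
    v[ETA_H] = p.eta_h
    v[ETA_C] = p.eta_c
    v[DECAY_H] = p.weight_decay_rate("HC")
    v[DECAY_C] = p.weight_decay_rate("CTX")
    v[TAU_S] = p.tau_s
    v[LAM] = p.lambda_(mode)
    v[DT_IDX] = p.dt
    v[SIGMA_A] = p.sigma_a(mode)
    v[THR] = p.recall_threshold
    v[COACT] = p.coactivation_threshold
    v[M_ORD] = float(p.m)
    v[N_ORD] = float(p.n)
    return v
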