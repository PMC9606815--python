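"""Compiled forward-Euler kernel for long simulation segments.

Semantics are identical to the reference path (:func:`seqreplay.dynamics.
step_network` + :func:`seqreplay.plasticity.update_weights` +
:func:`seqreplay.plasticity.instantiate_links` + the salience update); a
regression test integrates both paths side by side.  Per step:

1. excitatory/inhibitory inputs and analytic derivatives from the
   pre-update state (hippocampus sees previous-step cortical activation);
2. weight update from the same pre-update snapshot (passive decay always,
   Hebbian/depression terms only when the region's learning gate is on);
3. synchronous Euler update of activations and inactivation currents,
   clamped to [0, 1], with upward recall-threshold crossings recorded
   (same-step ties ordered by descending activation);
4. link instantiation from post-update co-activations (wake training only);
5. salience update from post-update cortical activations (wake only).
"""

import numpy as np
from numba import njit

from .params import (ALPHA, BETA, COACT, DECAY_C, DECAY_H, DT_IDX, ETA_C,
                     ETA_H, GAMMA, KAPPA, LAM, M_ORD, MU_C, MU_H, N_ORD,
                     Q_IDX, SIGMA_A, SIGMA_G, T_A, T_H, TAU_A, TAU_G, TAU_S,
                     THETA, THR, ZETA)

__all__ = ["run_segment"]


@njit(cache=True)
def _pow_ord(v, order):
    if order == 2.0:
        return v * v
    return v ** order


@njit(cache=True)
def run_segment(ac, gc, ah, gh, Wc, Wh, exc, exh, s,
                drive_item, drive_amp, n_steps, p,
                learn_c, learn_h, allow_links, hc_to_ctx, wake,
                ci_c, ct_c, ci_h, ct_h, ncc0, nch0,
                crossed_stop, stop_on, step_offset):
    """Integrate ``n_steps`` with constant drive; mutates state in place.

    ``ci_*/ct_*`` are preallocated crossing buffers (item index, absolute
    step) already holding ``ncc0``/``nch0`` entries.  ``crossed_stop`` is an
    int8 vector: -1 for items outside the stop set, 0 for stop-set items not
    yet crossed (cortex), 1 once crossed; when ``stop_on`` and no entry is 0,
    integration stops early.  Returns ``(ncc, nch, steps_done)``.
    """
    n = ac.shape[0]
    dt = p[DT_IDX]
    sa = p[SIGMA_A]
    m_ord = p[M_ORD]
    n_ord = p[N_ORD]
    tam = _pow_ord(p[T_A], m_ord)
    thn = _pow_ord(p[T_H], n_ord)
    thr = p[THR]
    coact = p[COACT]

    Ec = np.empty(n)
    Eh = np.empty(n)
    Ic = np.empty(n)
    Ih = np.empty(n)
    dac = np.empty(n)
    dah = np.empty(n)
    dgc = np.empty(n)
    dgh = np.empty(n)
    idx_tmp = np.empty(n, dtype=np.int64)

    ncc = ncc0
    nch = nch0
    cap_c = ci_c.shape[0]
    cap_h = ci_h.shape[0]
    steps_done = 0

    for step in range(n_steps):
        sum_ac = 0.0
        sum_ah = 0.0
        for x in range(n):
            sum_ac += ac[x]
            sum_ah += ah[x]

        for x in range(n):
            rec_c = 0.0
            rec_h = 0.0
            for y in range(n):
                rec_c += Wc[y, x] * ac[y]
                rec_h += Wh[y, x] * ah[y]
            am = _pow_ord(ac[x], m_ord)
            e = p[GAMMA] * rec_c + p[ALPHA] * am / (am + tam)
            if x == drive_item:
                e += p[MU_C] * drive_amp
            if hc_to_ctx and ah[x] > 0.0:
                e += p[ZETA] * ah[x]
            Ec[x] = e
            gn = _pow_ord(gc[x], n_ord)
            Ic[x] = p[BETA] * (sum_ac - ac[x]) + p[THETA] * gn / (gn + thn)

            am = _pow_ord(ah[x], m_ord)
            Eh[x] = (p[MU_H] * ac[x] + p[GAMMA] * rec_h
                     + p[ALPHA] * am / (am + tam))
            gn = _pow_ord(gh[x], n_ord)
            Ih[x] = p[BETA] * (sum_ah - ah[x]) + p[THETA] * gn / (gn + thn)

        for x in range(n):
            dac[x] = (-ac[x] / p[TAU_A] + (1.0 - ac[x]) * Ec[x]
                      - ac[x] * Ic[x]) / sa
            dah[x] = (-ah[x] / p[TAU_A] + (1.0 - ah[x]) * Eh[x]
                      - ah[x] * Ih[x]) / sa
            dgc[x] = (-gc[x] / p[TAU_G]
                      + (1.0 - gc[x]) * p[KAPPA] * ac[x]) / p[SIGMA_G]
            dgh[x] = (-gh[x] / p[TAU_G]
                      + (1.0 - gh[x]) * p[KAPPA] * ah[x]) / p[SIGMA_G]

        # -- plasticity from the pre-update snapshot ----------------------
        for x in range(n):
            axc = ac[x]
            axh = ah[x]
            for y in range(n):
                if exc[x, y]:
                    w = Wc[x, y]
                    dw = -w * p[DECAY_C]
                    if learn_c:
                        d = dac[y]
                        br = d if d > 0.0 else p[Q_IDX] * d
                        dw += p[ETA_C] * axc * (1.0 - w) * br
                    w += dt * dw
                    if w < 0.0:
                        w = 0.0
                    elif w > 1.0:
                        w = 1.0
                    Wc[x, y] = w
                if exh[x, y]:
                    w = Wh[x, y]
                    dw = -w * p[DECAY_H]
                    if learn_h:
                        d = dah[y]
                        br = d if d > 0.0 else p[Q_IDX] * d
                        dw += p[ETA_H] * axh * (1.0 - w) * br
                    w += dt * dw
                    if w < 0.0:
                        w = 0.0
                    elif w > 1.0:
                        w = 1.0
                    Wh[x, y] = w

        # -- synchronous state update with crossing detection -------------
        n_new_c = 0
        for x in range(n):
            prev = ac[x]
            v = prev + dt * dac[x]
            if v < 0.0:
                v = 0.0
            elif v > 1.0:
                v = 1.0
            ac[x] = v
            if prev < thr and v >= thr:
                idx_tmp[n_new_c] = x
                n_new_c += 1
            v = gc[x] + dt * dgc[x]
            gc[x] = 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)
        if n_new_c > 0:
            # order same-step crossings by descending post-update activation
            for i in range(1, n_new_c):
                key = idx_tmp[i]
                j = i - 1
                while j >= 0 and ac[idx_tmp[j]] < ac[key]:
                    idx_tmp[j + 1] = idx_tmp[j]
                    j -= 1
                idx_tmp[j + 1] = key
            for i in range(n_new_c):
                x = idx_tmp[i]
                if ncc < cap_c:
                    ci_c[ncc] = x
                    ct_c[ncc] = step_offset + step
                    ncc += 1
                if crossed_stop[x] == 0:
                    crossed_stop[x] = 1

        n_new_h = 0
        for x in range(n):
            prev = ah[x]
            v = prev + dt * dah[x]
            if v < 0.0:
                v = 0.0
            elif v > 1.0:
                v = 1.0
            ah[x] = v
            if prev < thr and v >= thr:
                idx_tmp[n_new_h] = x
                n_new_h += 1
            v = gh[x] + dt * dgh[x]
            gh[x] = 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)
        if n_new_h > 0:
            for i in range(1, n_new_h):
                key = idx_tmp[i]
                j = i - 1
                while j >= 0 and ah[idx_tmp[j]] < ah[key]:
                    idx_tmp[j + 1] = idx_tmp[j]
                    j -= 1
                idx_tmp[j + 1] = key
            for i in range(n_new_h):
                if nch < cap_h:
                    ci_h[nch] = idx_tmp[i]
                    ct_h[nch] = step_offset + step
                    nch += 1

        # -- link instantiation from post-update co-activations ------------
        if allow_links:
            for x in range(n):
                if ac[x] > coact:
                    for y in range(x + 1, n):
                        if ac[y] > coact and not exc[x, y]:
                            exc[x, y] = True
                            exc[y, x] = True
                if ah[x] > coact:
                    for y in range(x + 1, n):
                        if ah[y] > coact and not exh[x, y]:
                            exh[x, y] = True
                            exh[y, x] = True

        # -- salience from post-update cortical activations (wake only) ----
        if wake:
            for x in range(n):
                sv = s[x] + dt * (-s[x] / p[TAU_S] + p[LAM] * ac[x])
                s[x] = sv if sv > 0.0 else 0.0

        steps_done = step + 1

        if stop_on:
            done = True
            for x in range(n):
                if crossed_stop[x] == 0:
                    done = False
                    break
            if done:
                break

    return ncc, nch, steps_done
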