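"""Compiled multi-channel kernels for the Monte-Carlo experiment harness.

These numba kernels implement exactly the per-channel recursions of
:mod:`ratecal.filters` and :mod:`ratecal.decoders` (rank-one Sherman–Morrison
form of the information updates), specialised for speed: channels are
conditionally independent, so one loop over time with an inner loop over
channels reproduces the reference implementations bit-for-bit up to floating
point reassociation.  Equivalence against the reference single-channel
functions is asserted in the test suite.

All stochastic draws happen inside the kernels from an explicit integer seed,
in a fixed (time, channel) order, so that sweeps over learning rates can share
common random numbers by sharing seeds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["kf_adapt_batch", "ppf_adapt_batch", "kf_closed_loop", "ppf_closed_loop"]

_LOG_CAP = 50.0


@njit(cache=True)
def kf_adapt_batch(V, psi_star, psi0, Z, s, S0, seed, win_start, bounds,
                   estimate_Z, Lwin, z_init, g_sum, gg_sum, err_acc, thin):
    """Adaptive KF over C channels for a whole session.

    ``err_acc`` (ceil(T/thin), C, n, float32) accumulates the error vectors at
    every ``thin``-th step across replicate calls so the caller can estimate
    the expected-error decay ``E[g_t]`` per channel.  ``g_sum``/``gg_sum`` accumulate first/second
    error moments over ``t >= win_start`` (in place, so replicates pool).
    Returns ``(n_in_bounds, n_total, Z_final, psi_final)``.
    """
    T, n = V.shape
    C = psi_star.shape[0]
    np.random.seed(seed)

    psi = psi0.copy()
    S = S0.copy()
    # covariance-matching ring buffers (only touched when estimate_Z)
    qbuf = np.zeros((C, Lwin))
    pbuf = np.zeros((C, Lwin))
    sq = np.zeros(C)
    sq2 = np.zeros(C)
    sp = np.zeros(C)
    zcount = 0
    zidx = 0
    z_floor = 1e-6 * z_init
    Zc = np.empty(C)
    for c in range(C):
        Zc[c] = z_init if estimate_Z else Z[c]

    Pv = np.empty(n)
    n_in = 0
    n_tot = 0
    for t in range(T):
        full = zcount == Lwin
        for c in range(C):
            # prediction step: mean unchanged, covariance inflated by s I
            for i in range(n):
                S[c, i, i] += s
            # simulate the observation from the true channel
            mean_y = 0.0
            pred_y = 0.0
            for i in range(n):
                mean_y += psi_star[c, i] * V[t, i]
                pred_y += psi[c, i] * V[t, i]
            y = mean_y + np.sqrt(Z[c]) * np.random.normal()
            if estimate_Z:
                # covariance matching on the innovation, right after prediction
                q = y - pred_y
                p = 0.0
                for i in range(n):
                    acc = 0.0
                    for j in range(n):
                        acc += S[c, i, j] * V[t, j]
                    p += V[t, i] * acc
                if full:
                    old_q = qbuf[c, zidx]
                    old_p = pbuf[c, zidx]
                    sq[c] -= old_q
                    sq2[c] -= old_q * old_q
                    sp[c] -= old_p
                qbuf[c, zidx] = q
                pbuf[c, zidx] = p
                sq[c] += q
                sq2[c] += q * q
                sp[c] += p
                cnt = Lwin if full else zcount + 1
                if cnt >= 2:
                    var = (sq2[c] - sq[c] * sq[c] / cnt) / (cnt - 1)
                    est = var - sp[c] / cnt
                    Zc[c] = est if est > z_floor else z_floor
            # rank-one update (Sherman-Morrison form of the information update)
            a = 0.0
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    acc += S[c, i, j] * V[t, j]
                Pv[i] = acc
                a += V[t, i] * acc
            denom = Zc[c] + a
            innov = y - pred_y
            for i in range(n):
                psi[c, i] += Pv[i] / denom * innov
            for i in range(n):
                for j in range(i, n):
                    val = S[c, i, j] - Pv[i] * Pv[j] / denom
                    S[c, i, j] = val
                    S[c, j, i] = val
            # error bookkeeping
            for i in range(n):
                g = psi_star[c, i] - psi[c, i]
                if t % thin == 0:
                    err_acc[t // thin, c, i] += g
                if t >= win_start:
                    g_sum[c, i] += g
                    n_tot += 1
                    if abs(g) <= bounds[c, i]:
                        n_in += 1
            if t >= win_start:
                for i in range(n):
                    gi = psi_star[c, i] - psi[c, i]
                    for j in range(n):
                        gg_sum[c, i, j] += gi * (psi_star[c, j] - psi[c, j])
        if estimate_Z:
            zidx += 1
            if zidx == Lwin:
                zidx = 0
            if zcount < Lwin:
                zcount += 1
    return n_in, n_tot, Zc, psi


@njit(cache=True)
def ppf_adapt_batch(V, phi_star, phi0, delta, r, Q0, seed, win_start,
                    bounds, g_sum, gg_sum, err_acc, thin):
    """Adaptive PPF over C neurons for a whole session (spikes drawn inside)."""
    T, n = V.shape
    C = phi_star.shape[0]
    np.random.seed(seed)

    phi = phi0.copy()
    Q = Q0.copy()
    Pv = np.empty(n)
    n_in = 0
    n_tot = 0
    for t in range(T):
        for c in range(C):
            for i in range(n):
                Q[c, i, i] += r
            log_true = 0.0
            log_hat = 0.0
            for i in range(n):
                log_true += phi_star[c, i] * V[t, i]
                log_hat += phi[c, i] * V[t, i]
            if log_true > _LOG_CAP:
                log_true = _LOG_CAP
            if log_hat > _LOG_CAP:
                log_hat = _LOG_CAP
            p_spike = np.exp(log_true) * delta
            if p_spike > 1.0:
                p_spike = 1.0
            N = 1.0 if np.random.random() < p_spike else 0.0
            w = np.exp(log_hat) * delta
            a = 0.0
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    acc += Q[c, i, j] * V[t, j]
                Pv[i] = acc
                a += V[t, i] * acc
            denom = 1.0 + w * a
            innov = N - w
            for i in range(n):
                phi[c, i] += Pv[i] / denom * innov
            for i in range(n):
                for j in range(i, n):
                    val = Q[c, i, j] - w * Pv[i] * Pv[j] / denom
                    Q[c, i, j] = val
                    Q[c, j, i] = val
            for i in range(n):
                g = phi_star[c, i] - phi[c, i]
                if t % thin == 0:
                    err_acc[t // thin, c, i] += g
                if t >= win_start:
                    g_sum[c, i] += g
                    n_tot += 1
                    if abs(g) <= bounds[c, i]:
                        n_in += 1
            if t >= win_start:
                for i in range(n):
                    gi = phi_star[c, i] - phi[c, i]
                    for j in range(n):
                        gg_sum[c, i, j] += gi * (phi_star[c, j] - phi[c, j])
    return n_in, n_tot, phi


@njit(cache=True)
def _decoder_predict(x, P, delta, alpha, wvar):
    # kinematic prior: d += delta v, v *= alpha, noise on velocity only
    x_new = np.empty(4)
    x_new[0] = x[0] + delta * x[2]
    x_new[1] = x[1] + delta * x[3]
    x_new[2] = alpha * x[2]
    x_new[3] = alpha * x[3]
    A = np.zeros((4, 4))
    A[0, 0] = 1.0
    A[1, 1] = 1.0
    A[0, 2] = delta
    A[1, 3] = delta
    A[2, 2] = alpha
    A[3, 3] = alpha
    P_new = A @ P @ A.T
    P_new[2, 2] += wvar
    P_new[3, 3] += wvar
    return x_new, 0.5 * (P_new + P_new.T)


@njit(cache=True)
def kf_closed_loop(targets, Lgain, delta, alpha, wstd, dec_wstd, v_cap,
                   psi_star, Z, s, adapt, psi_hat, S_hat, dec_params, x_dec,
                   P_dec, v_int, seed):
    """Closed-loop segment with continuous channels and a KF velocity decoder.

    The OFC subject acts on the decoded cursor state; neural features encode
    its intended velocity; the adaptive KF (if ``adapt``) consumes the
    intended velocity as the supervised encoded state.  ``psi_hat``/``S_hat``,
    ``x_dec``/``P_dec``/``v_int`` persist across segments (updated in place).
    ``dec_params`` are the parameters the decoder uses this segment (alias of
    ``psi_hat`` while adapting, a frozen copy when evaluating).

    Returns the decoded positions and intended velocities, (T, 2) each.
    """
    T = targets.shape[0]
    C = psi_star.shape[0]
    np.random.seed(seed)
    dec_wvar = dec_wstd * dec_wstd
    decoded = np.empty((T, 2))
    intended = np.empty((T, 2))
    v = np.empty(3)
    Pv = np.empty(3)
    h = np.empty(4)
    for t in range(T):
        # subject: control from decoded state toward the active target
        u0 = 0.0
        u1 = 0.0
        for j in range(4):
            xs = x_dec[j]
            if j < 2:
                xs -= targets[t, j]
            u0 -= Lgain[0, j] * xs
            u1 -= Lgain[1, j] * xs
        v_int[0] = alpha * v_int[0] + u0 + wstd * np.random.normal()
        v_int[1] = alpha * v_int[1] + u1 + wstd * np.random.normal()
        # intended speed is physiologically bounded; keeps an unstable
        # decoder loop from running away exponentially
        speed = np.sqrt(v_int[0] * v_int[0] + v_int[1] * v_int[1])
        if speed > v_cap:
            v_int[0] *= v_cap / speed
            v_int[1] *= v_cap / speed
        v[0] = 1.0
        v[1] = v_int[0]
        v[2] = v_int[1]
        # decoder prediction
        x_pred, P = _decoder_predict(x_dec, P_dec, delta, alpha, dec_wvar)
        for j in range(4):
            x_dec[j] = x_pred[j]
        for c in range(C):
            mean_y = 0.0
            for i in range(3):
                mean_y += psi_star[c, i] * v[i]
            y = mean_y + np.sqrt(Z[c]) * np.random.normal()
            if adapt:
                # adaptive KF on (v_int, y), learning rate s, known Z
                for i in range(3):
                    S_hat[c, i, i] += s
                a = 0.0
                pred_y = 0.0
                for i in range(3):
                    acc = 0.0
                    for j in range(3):
                        acc += S_hat[c, i, j] * v[j]
                    Pv[i] = acc
                    a += v[i] * acc
                    pred_y += psi_hat[c, i] * v[i]
                denom = Z[c] + a
                innov = y - pred_y
                for i in range(3):
                    psi_hat[c, i] += Pv[i] / denom * innov
                for i in range(3):
                    for j in range(i, 3):
                        val = S_hat[c, i, j] - Pv[i] * Pv[j] / denom
                        S_hat[c, i, j] = val
                        S_hat[c, j, i] = val
            # decoder update from this channel (velocity coupling only)
            h[0] = 0.0
            h[1] = 0.0
            h[2] = dec_params[c, 1]
            h[3] = dec_params[c, 2]
            Ph0 = P[0, 2] * h[2] + P[0, 3] * h[3]
            Ph1 = P[1, 2] * h[2] + P[1, 3] * h[3]
            Ph2 = P[2, 2] * h[2] + P[2, 3] * h[3]
            Ph3 = P[3, 2] * h[2] + P[3, 3] * h[3]
            dden = Z[c] + h[2] * Ph2 + h[3] * Ph3
            resid = y - dec_params[c, 0] - h[2] * x_dec[2] - h[3] * x_dec[3]
            x_dec[0] += Ph0 / dden * resid
            x_dec[1] += Ph1 / dden * resid
            x_dec[2] += Ph2 / dden * resid
            x_dec[3] += Ph3 / dden * resid
            P[0, 0] -= Ph0 * Ph0 / dden
            P[0, 1] -= Ph0 * Ph1 / dden
            P[0, 2] -= Ph0 * Ph2 / dden
            P[0, 3] -= Ph0 * Ph3 / dden
            P[1, 1] -= Ph1 * Ph1 / dden
            P[1, 2] -= Ph1 * Ph2 / dden
            P[1, 3] -= Ph1 * Ph3 / dden
            P[2, 2] -= Ph2 * Ph2 / dden
            P[2, 3] -= Ph2 * Ph3 / dden
            P[3, 3] -= Ph3 * Ph3 / dden
            for i in range(4):
                for j in range(i + 1, 4):
                    P[i, j] = 0.5 * (P[i, j] + P[j, i])
                    P[j, i] = P[i, j]
        for i in range(4):
            for j in range(4):
                P_dec[i, j] = P[i, j]
        decoded[t, 0] = x_dec[0]
        decoded[t, 1] = x_dec[1]
        intended[t, 0] = v_int[0]
        intended[t, 1] = v_int[1]
    return decoded, intended


@njit(cache=True)
def ppf_closed_loop(targets, Lgain, delta, alpha, wstd, dec_wstd, v_cap,
                    phi_star, r, adapt, phi_hat, Q_hat, dec_params, x_dec,
                    P_dec, v_int, seed):
    """Closed-loop segment with spiking neurons and a PPF velocity decoder."""
    T = targets.shape[0]
    C = phi_star.shape[0]
    np.random.seed(seed)
    dec_wvar = dec_wstd * dec_wstd
    decoded = np.empty((T, 2))
    intended = np.empty((T, 2))
    v = np.empty(3)
    Pv = np.empty(3)
    for t in range(T):
        u0 = 0.0
        u1 = 0.0
        for j in range(4):
            xs = x_dec[j]
            if j < 2:
                xs -= targets[t, j]
            u0 -= Lgain[0, j] * xs
            u1 -= Lgain[1, j] * xs
        v_int[0] = alpha * v_int[0] + u0 + wstd * np.random.normal()
        v_int[1] = alpha * v_int[1] + u1 + wstd * np.random.normal()
        # intended speed is physiologically bounded; keeps an unstable
        # decoder loop from running away exponentially
        speed = np.sqrt(v_int[0] * v_int[0] + v_int[1] * v_int[1])
        if speed > v_cap:
            v_int[0] *= v_cap / speed
            v_int[1] *= v_cap / speed
        v[0] = 1.0
        v[1] = v_int[0]
        v[2] = v_int[1]
        x_pred, P = _decoder_predict(x_dec, P_dec, delta, alpha, dec_wvar)
        for j in range(4):
            x_dec[j] = x_pred[j]
        for c in range(C):
            log_true = 0.0
            for i in range(3):
                log_true += phi_star[c, i] * v[i]
            if log_true > _LOG_CAP:
                log_true = _LOG_CAP
            p_spike = np.exp(log_true) * delta
            if p_spike > 1.0:
                p_spike = 1.0
            N = 1.0 if np.random.random() < p_spike else 0.0
            if adapt:
                for i in range(3):
                    Q_hat[c, i, i] += r
                log_hat = 0.0
                for i in range(3):
                    log_hat += phi_hat[c, i] * v[i]
                if log_hat > _LOG_CAP:
                    log_hat = _LOG_CAP
                w = np.exp(log_hat) * delta
                a = 0.0
                for i in range(3):
                    acc = 0.0
                    for j in range(3):
                        acc += Q_hat[c, i, j] * v[j]
                    Pv[i] = acc
                    a += v[i] * acc
                denom = 1.0 + w * a
                innov = N - w
                for i in range(3):
                    phi_hat[c, i] += Pv[i] / denom * innov
                for i in range(3):
                    for j in range(i, 3):
                        val = Q_hat[c, i, j] - w * Pv[i] * Pv[j] / denom
                        Q_hat[c, i, j] = val
                        Q_hat[c, j, i] = val
            # decoder update (Laplace, velocity coupling only)
            g2 = dec_params[c, 1]
            g3 = dec_params[c, 2]
            log_dec = dec_params[c, 0] + g2 * x_dec[2] + g3 * x_dec[3]
            if log_dec > _LOG_CAP:
                log_dec = _LOG_CAP
            w = np.exp(log_dec) * delta
            Pg0 = P[0, 2] * g2 + P[0, 3] * g3
            Pg1 = P[1, 2] * g2 + P[1, 3] * g3
            Pg2 = P[2, 2] * g2 + P[2, 3] * g3
            Pg3 = P[3, 2] * g2 + P[3, 3] * g3
            dden = 1.0 + w * (g2 * Pg2 + g3 * Pg3)
            fac = w / dden
            P[0, 0] -= Pg0 * Pg0 * fac
            P[0, 1] -= Pg0 * Pg1 * fac
            P[0, 2] -= Pg0 * Pg2 * fac
            P[0, 3] -= Pg0 * Pg3 * fac
            P[1, 1] -= Pg1 * Pg1 * fac
            P[1, 2] -= Pg1 * Pg2 * fac
            P[1, 3] -= Pg1 * Pg3 * fac
            P[2, 2] -= Pg2 * Pg2 * fac
            P[2, 3] -= Pg2 * Pg3 * fac
            P[3, 3] -= Pg3 * Pg3 * fac
            for i in range(4):
                for j in range(i + 1, 4):
                    P[i, j] = 0.5 * (P[i, j] + P[j, i])
                    P[j, i] = P[i, j]
            innov = N - w
            x_dec[0] += (P[0, 2] * g2 + P[0, 3] * g3) * innov
            x_dec[1] += (P[1, 2] * g2 + P[1, 3] * g3) * innov
            x_dec[2] += (P[2, 2] * g2 + P[2, 3] * g3) * innov
            x_dec[3] += (P[3, 2] * g2 + P[3, 3] * g3) * innov
        for i in range(4):
            for j in range(4):
                P_dec[i, j] = P[i, j]
        decoded[t, 0] = x_dec[0]
        decoded[t, 1] = x_dec[1]
        intended[t, 0] = v_int[0]
        intended[t, 1] = v_int[1]
    return decoded, intended
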