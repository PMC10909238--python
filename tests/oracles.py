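"""Independent scalar transcriptions of the optimizer update rules.

These re-derive one iteration of each algorithm with explicit per-individual,
per-coordinate loops, sharing only the documented random-draw protocol with
the vectorized implementations they check.  Kept free of any import from the
package's optimizer internals beyond the config dataclasses.
"""

import numpy as np


def scalar_dto_step(P, V, P_best, f_best, P_Gbest, lower, upper, K4, K5, k_range, rng):
    """One DTO iteration, straight-line: returns (P_new, V_new).

    Draw protocol: r = rng.random((m, 3)) then K = rng.uniform(*k_range, (m, 3)).
    """
    m, d = P.shape
    r = rng.random((m, 3))
    K = rng.uniform(k_range[0], k_range[1], size=(m, 3))
    P_new = np.empty_like(P)
    V_new = np.empty_like(V)
    for i in range(m):
        r1, r2, r3 = r[i]
        K1, K2, K3 = K[i]
        for j in range(d):
            x = P_best[i, j] - K1 * abs(K2 * P_best[i, j] - P[i, j])
            v = (
                K3 * V[i, j]
                + K4 * r1 * (P_best[i, j] - P[i, j])
                + K5 * r2 * (P_Gbest[j] - P[i, j])
            )
            y = P[i, j] + v
            V_new[i, j] = v
            P_new[i, j] = x if r3 < 0.5 else y
            P_new[i, j] = min(max(P_new[i, j], lower[j]), upper[j])
    return P_new, V_new


def scalar_sca_step(P, best, t, T, a, rng):
    """One SCA position update, straight-line (no clipping).

    Draw protocol: r2 ~ U(0, 2pi), r3 ~ U(0, 2), r4 ~ U(0, 1), each (m, d).
    """
    m, d = P.shape
    r2 = rng.uniform(0.0, 2.0 * np.pi, size=(m, d))
    r3 = rng.uniform(0.0, 2.0, size=(m, d))
    r4 = rng.random((m, d))
    out = np.empty_like(P)
    for i in range(m):
        for j in range(d):
            r1 = a * (1.0 - t / T)
            step = abs(r3[i, j] * best[j] - P[i, j])
            if r4[i, j] < 0.5:
                out[i, j] = P[i, j] + r1 * np.sin(r2[i, j]) * step
            else:
                out[i, j] = P[i, j] + r1 * np.cos(r2[i, j]) * step
    return out


def scalar_firefly_move(xi, xj, t, beta0, gamma, alpha0, alpha_decay, rng):
    """One firefly attraction move, straight-line."""
    d = len(xi)
    r2 = sum((xj[k] - xi[k]) ** 2 for k in range(d))
    out = np.empty(d)
    kappa = rng.standard_normal(d) if alpha0 > 0 else np.zeros(d)
    for k in range(d):
        attract = beta0 * np.exp(-gamma * r2) * (xj[k] - xi[k])
        jitter = alpha0 * alpha_decay**t * (kappa[k] - 0.5) if alpha0 > 0 else 0.0
        out[k] = xi[k] + attract + jitter
    return out


def scalar_msca_step(P, f, P_Gbest, t, cfg, lower, upper, rng_move, rng_fa):
    """One MSCA position update, straight-line: SCA field drawn for all rows
    from rng_move, then phi and firefly jitter from rng_fa for active rows."""
    m, d = P.shape
    sca = scalar_sca_step(P, P_Gbest, t, cfg.T, cfg.a, rng_move)
    new = sca.copy()
    if t >= cfg.activation_fraction * cfg.T:
        phi = rng_fa.random(m)
        for i in range(m):
            if phi[i] > cfg.phi_threshold:
                new[i] = scalar_firefly_move(
                    P[i], P_Gbest, t, cfg.beta0, cfg.gamma, cfg.alpha0, cfg.alpha_decay, rng_fa
                )
    for i in range(m):
        for j in range(d):
            new[i, j] = min(max(new[i, j], lower[j]), upper[j])
    return new
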