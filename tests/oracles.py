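"""Independent scalar-loop reference implementations.

Everything here is deliberately written with per-neuron Python loops and
``math`` scalars — no numpy vectorisation — so it shares no code path
with the package.  Used to cross-check the vectorised dynamics, the
forward pass, and the composed learning update.
"""

from __future__ import annotations

import numpy as np


def lif_step_scalar(V, g_E, drive, p):
    """One LIF step for lists of per-neuron scalars.

    Same update ordering as the package (voltage from pre-update
    conductance, then conductance relaxation, then strict threshold and
    reset, then surrogate), but evaluated neuron by neuron in pure
    Python arithmetic.
    """
    n = len(V)
    V2, g2, d2, S2 = [0.0] * n, [0.0] * n, [0.0] * n, [0.0] * n
    for i in range(n):
        v = V[i] - (p.dt / p.tau_m) * ((V[i] - p.V_L) + (g_E[i] / p.g_L) * (V[i] - p.V_E))
        g2[i] = g_E[i] + (p.dt / p.tau_E) * (-g_E[i] + drive[i])
        if v > p.V_th:
            d2[i] = 1.0
            v = p.V_reset
        V2[i] = v
        S2[i] = drive[i] + p.tau_s * d2[i]
    return V2, g2, d2, S2


def forward_scalar(layer_sizes, weights, x, p):
    """Whole forward pass for ONE sample, all loops explicit.

    Returns the list of final-step surrogate outputs per layer
    (input first), mirroring the package's ascending-within-step
    scheduling.
    """
    L = len(layer_sizes)
    n_steps = int(round(p.T / p.dt))
    V = [[p.V_reset] * layer_sizes[l] for l in range(1, L)]
    g = [[0.0] * layer_sizes[l] for l in range(1, L)]
    S = [[0.0] * layer_sizes[l] for l in range(1, L)]
    x = list(map(float, x))
    for _t in range(n_steps):
        S_prev = x
        for li in range(L - 1):
            W = weights[li]
            n_post = layer_sizes[li + 1]
            drive = [
                sum(S_prev[j] * W[j][i] for j in range(layer_sizes[li]))
                for i in range(n_post)
            ]
            V[li], g[li], _d, S[li] = lif_step_scalar(V[li], g[li], drive, p)
            S_prev = S[li]
    return [x] + [list(s) for s in S]


def one_update_scalar(layer_sizes, weights, x, label, p, eta_t, eta_w, B=None, b=None):
    """One full learning step for ONE sample, composed by hand.

    Forward pass, signed output error, penultimate target by transpose
    pullback, optional random-feedback hidden targets, outer-product
    weight deltas, plain gradient step.  Returns the updated weight
    matrices as nested lists.
    """
    L = len(layer_sizes)
    n_out = layer_sizes[-1]
    S = forward_scalar(layer_sizes, weights, x, p)
    S_T = [1.0 if k == label else 0.0 for k in range(n_out)]
    e = [2.0 * (S[-1][k] - S_T[k]) for k in range(n_out)]

    targets = {L - 1: S_T}
    if L >= 3:
        W_out = weights[L - 2]
        pen = L - 2
        targets[pen] = [
            S[pen][i] - eta_t * sum(e[k] * W_out[i][k] for k in range(n_out))
            for i in range(layer_sizes[pen])
        ]
    if B is not None:
        for l in B:
            targets[l] = [
                S[l][i] - (sum(B[l][i][k] * e[k] for k in range(n_out)) + b[l][i])
                for i in range(layer_sizes[l])
            ]

    new_weights = []
    for li in range(L - 1):
        post = li + 1
        W = weights[li]
        if post not in targets:
            new_weights.append([row[:] for row in W])
            continue
        diff = [S[post][i] - targets[post][i] for i in range(layer_sizes[post])]
        new_weights.append(
            [
                [W[j][i] - eta_w * S[li][j] * diff[i] for i in range(layer_sizes[post])]
                for j in range(layer_sizes[li])
            ]
        )
    return new_weights


def nearest_centroid_accuracy(train_X, train_y, test_X, test_y) -> float:
    """Brute-force nearest-centroid classifier accuracy (%)."""
    classes = sorted(set(int(c) for c in train_y))
    cents = {c: train_X[train_y == c].mean(axis=0) for c in classes}
    correct = 0
    for x, y in zip(test_X, test_y):
        d = {c: float(((x - cents[c]) ** 2).sum()) for c in classes}
        if min(d, key=d.get) == int(y):
            correct += 1
    return 100.0 * correct / len(test_y)
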