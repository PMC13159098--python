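"""Independent reference implementations used as test oracles.

Everything here is written as plain hand-unrolled Python loops, deliberately
sharing no code with the package internals.
"""

import math

import numpy as np

_LN_EPS = 1e-6


def _gelu_scalar(x: float) -> float:
    return 0.5 * x * (1.0 + math.erf(x / math.sqrt(2.0)))


def _sigmoid_scalar(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _head_scalar(y, W1, b1, W2, b2, d, G):
    mu = sum(y) / d
    var = sum((v - mu) ** 2 for v in y) / d
    nrm = [(v - mu) / math.sqrt(var + _LN_EPS) for v in y]
    hid = [_gelu_scalar(sum(W1[i][j] * nrm[j] for j in range(d)) + b1[i])
           for i in range(d)]
    return [sum(W2[k][i] * hid[i] for i in range(d)) + b2[k] for k in range(G)]


def reference_forward(X, params):
    """Hand-unrolled gated causal recurrence with CLS aggregation and heads.

    Returns (local_outputs n x d, global_output d, local_predictions n x G,
    global_prediction G) as plain numpy arrays.
    """
    p = {k: np.asarray(v, float).tolist() for k, v in params.params.items()}
    d, G = params.d, params.G
    seq = [list(map(float, row)) for row in np.asarray(X, float)]
    seq.append(list(p["cls"]))
    h = [0.0] * d
    ys = []
    for x in seq:
        a = [sum(p["W_a"][j][k] * x[k] for k in range(d)) + p["b_a"][j]
             for j in range(d)]
        if params.sigmoid_decay:
            a = [_sigmoid_scalar(v) for v in a]
        b = [sum(p["W_b"][j][k] * x[k] for k in range(d)) + p["b_b"][j]
             for j in range(d)]
        c = [sum(p["W_c"][j][k] * x[k] for k in range(d)) + p["b_c"][j]
             for j in range(d)]
        g = [sum(p["W_g"][j][k] * x[k] for k in range(d)) + p["b_g"][j]
             for j in range(d)]
        h = [a[j] * h[j] + b[j] * x[j] for j in range(d)]
        ys.append([g[j] * (c[j] * h[j]) for j in range(d)])
    local = [_head_scalar(y, p["lW1"], p["lb1"], p["lW2"], p["lb2"], d, G)
             for y in ys[:-1]]
    glob = _head_scalar(ys[-1], p["gW1"], p["gb1"], p["gW2"], p["gb2"], d, G)
    return (np.array(ys[:-1]), np.array(ys[-1]), np.array(local), np.array(glob))


def pair_counting_auc(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair counting (ties count 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
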