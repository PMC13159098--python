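"""Gated causal-recurrence fusion backbone with CLS aggregation.

A slide is a sequence of patch embeddings x_1..x_n (d-dimensional).  Four
per-step coefficient vectors are produced by learned affine maps of the
input,

    a_i, b_i, c_i, g_i = Linear(x_i)

and the hidden state and per-step output follow the first-order causal
recurrence

    h_i = a_i * h_{i-1} + b_i * x_i        (elementwise, h_0 = 0)
    y_i = g_i * (c_i * h_i)

a_i acts as memory decay, b_i as input injection, c_i as read-out and g_i
as output gating.  A learnable CLS embedding is appended as the last
sequence element so its hidden state integrates the whole slide; its output
y_CLS feeds the global head while each patch output y_i feeds the local
head.  Both heads are independent two-layer MLPs (hidden width d, GELU,
with a parameter-free layer normalization on the input so the head sees a
scale-stable representation of the recurrence output) mapping to the
G-gene panel.

Everything here is plain NumPy (float64).  The backward pass is written
analytically and is checked against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

PARAM_KEYS = (
    "W_a", "b_a", "W_b", "b_b", "W_c", "b_c", "W_g", "b_g",
    "cls",
    "lW1", "lb1", "lW2", "lb2",
    "gW1", "gb1", "gW2", "gb2",
)


@dataclass
class FusionParams:
    """All learnable weights of the recurrence, CLS token and heads.

    ``params`` maps parameter names to float64 arrays: the four coefficient
    maps (``W_*`` are d x d, ``b_*`` are d), the CLS embedding (d), and the
    local/global heads (``lW1``/``gW1`` d x d, ``lW2``/``gW2`` G x d with
    matching biases).  The two heads never share weights.
    """

    d: int
    G: int
    params: dict[str, np.ndarray]
    sigmoid_decay: bool = False  # optional bounded memory-decay on a_i
    loss_reduce: str = "mean"  # 'mean' (per-gene mean) or 'sum' over genes
    meta: dict = field(default_factory=dict)  # gene panel, ordering, stage tag

    @classmethod
    def init(cls, d: int, G: int, seed: int = 0, *, sigmoid_decay: bool = False,
             loss_reduce: str = "mean", meta: dict | None = None,
             decay_bias: float = 0.0, gate_bias: float = 0.0,
             coeff_scale: float = 1.0) -> "FusionParams":
        """Seeded initialization: symmetric-uniform weights scaled by
        coeff_scale/sqrt(d) for the coefficient maps and 1/sqrt(d) for the
        heads; CLS from the same distribution.

        ``decay_bias`` / ``gate_bias`` preset the biases of the a map and of
        the b/c/g maps (pass-through gate initialization); the plain default
        is all-zero biases.
        """
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(d)
        p: dict[str, np.ndarray] = {}
        for k in ("W_a", "W_b", "W_c", "W_g"):
            p[k] = rng.uniform(-s * coeff_scale, s * coeff_scale, size=(d, d))
        for k in ("lW1", "gW1"):
            p[k] = rng.uniform(-s, s, size=(d, d))
        for k in ("lW2", "gW2"):
            p[k] = rng.uniform(-s, s, size=(G, d))
        p["b_a"] = np.full(d, float(decay_bias))
        for k in ("b_b", "b_c", "b_g"):
            p[k] = np.full(d, float(gate_bias))
        for k in ("lb1", "gb1"):
            p[k] = np.zeros(d)
        for k in ("lb2", "gb2"):
            p[k] = np.zeros(G)
        p["cls"] = rng.uniform(-s, s, size=d)
        return cls(d=d, G=G, params=p, sigmoid_decay=sigmoid_decay,
                   loss_reduce=loss_reduce, meta=dict(meta or {}))

    #: stage-appropriate decay-bias presets for training: the bulk model
    #: starts as a long-memory integrator (slide-wide aggregation), the spot
    #: model with short memory (per-spot readout dominates)
    TRAINING_DECAY_BIAS = {"bulk": 4.0, "spot": -2.0}

    @classmethod
    def for_training(cls, d: int, G: int, level: str, seed: int = 0,
                     meta: dict | None = None) -> "FusionParams":
        """Training-pipeline initialization: bounded sigmoid memory decay,
        pass-through gates (b/c/g biases at 1), damped coefficient weights
        and a level-appropriate decay timescale."""
        if level not in cls.TRAINING_DECAY_BIAS:
            raise ValueError("level must be 'bulk' or 'spot'")
        return cls.init(d, G, seed, sigmoid_decay=True, meta=meta,
                        decay_bias=cls.TRAINING_DECAY_BIAS[level],
                        gate_bias=1.0, coeff_scale=0.25)

    def copy(self) -> "FusionParams":
        return FusionParams(self.d, self.G, {k: v.copy() for k, v in self.params.items()},
                            self.sigmoid_decay, self.loss_reduce, dict(self.meta))

    def zeros_like(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    # -- checkpoint container: npz archive with an embedded JSON header -----
    def save(self, path, stage_tag: str = "", extra_header: dict | None = None) -> None:
        header = {
            "d": self.d, "G": self.G,
            "sigmoid_decay": self.sigmoid_decay,
            "loss_reduce": self.loss_reduce,
            "stage_tag": stage_tag,
            **self.meta,
            **(extra_header or {}),
        }
        arrays = dict(self.params)
        arrays["__header__"] = np.frombuffer(
            json.dumps(header, sort_keys=True).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> tuple["FusionParams", dict]:
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            params = {k: z[k] for k in z.files if k != "__header__"}
        fp = cls(d=int(header["d"]), G=int(header["G"]), params=params,
                 sigmoid_decay=bool(header.get("sigmoid_decay", False)),
                 loss_reduce=header.get("loss_reduce", "mean"))
        fp.meta = {k: v for k, v in header.items()
                   if k not in ("d", "G", "sigmoid_decay", "loss_reduce")}
        return fp, header


@dataclass
class SequenceOutput:
    """Forward-pass outputs for one slide."""

    local_outputs: np.ndarray      # n x d  (y_1..y_n)
    global_output: np.ndarray      # d      (y_CLS)
    local_predictions: np.ndarray  # n x G  (z-hat_i)
    global_prediction: np.ndarray  # G      (z-hat_global)


def _check_finite(x: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(f"non-finite values in {what}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * phi


def coefficients(x: np.ndarray, params: FusionParams):
    """The four per-step coefficient vectors a, b, c, g for one input x.

    Raw affine outputs by default; if ``sigmoid_decay`` is set, a is squashed
    to (0, 1) for a bounded memory decay.
    """
    x = np.asarray(x, dtype=float)
    _check_finite(x, "input")
    p = params.params
    a = p["W_a"] @ x + p["b_a"]
    if params.sigmoid_decay:
        a = _sigmoid(a)
    b = p["W_b"] @ x + p["b_b"]
    c = p["W_c"] @ x + p["b_c"]
    g = p["W_g"] @ x + p["b_g"]
    return a, b, c, g


def recurrence_step(h_prev: np.ndarray, x: np.ndarray, params: FusionParams):
    """One causal update: h = a*h_prev + b*x, y = g*(c*h)."""
    h_prev = np.asarray(h_prev, dtype=float)
    _check_finite(h_prev, "hidden state")
    a, b, c, g = coefficients(x, params)
    h = a * h_prev + b * x
    y = g * (c * h)
    _check_finite(h, "hidden state update")
    return h, y


_LN_EPS = 1e-6


def _layernorm(Y: np.ndarray):
    mu = Y.mean(axis=-1, keepdims=True)
    xc = Y - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    return xc * inv, xc, inv


def _layernorm_backward(dN, xc, inv):
    d = xc.shape[-1]
    dxc = dN * inv - xc * (inv ** 3) * (dN * xc).mean(axis=-1, keepdims=True)
    return dxc - dxc.mean(axis=-1, keepdims=True)


def _head_forward(Y: np.ndarray, W1, b1, W2, b2):
    # parameter-free layer normalization keeps the head input scale
    # independent of the recurrence magnitude
    N, xc, inv = _layernorm(Y)
    pre = N @ W1.T + b1
    act = _gelu(pre)
    out = act @ W2.T + b2
    return out, pre, act, N, xc, inv


class _ForwardCache:
    __slots__ = ("X_full", "A_raw", "A", "B", "C", "Gt", "H", "Hprev",
                 "Y", "l_pre", "l_act", "l_N", "l_xc", "l_inv",
                 "g_pre", "g_act", "g_N", "g_xc", "g_inv")


def _forward_full(X: np.ndarray, params: FusionParams):
    """Run the recurrence over [x_1..x_n, CLS] and both heads, keeping the
    intermediate values needed by the backward pass."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.d:
        raise ValueError(f"expected n x {params.d} embeddings, got {X.shape}")
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty patch sequence")
    _check_finite(X, "embeddings")
    p = params.params
    X_full = np.vstack([X, p["cls"][None, :]])  # CLS appended last
    A_raw = X_full @ p["W_a"].T + p["b_a"]
    A = _sigmoid(A_raw) if params.sigmoid_decay else A_raw
    B = X_full @ p["W_b"].T + p["b_b"]
    C = X_full @ p["W_c"].T + p["b_c"]
    Gt = X_full @ p["W_g"].T + p["b_g"]
    n1 = n + 1
    H = np.empty_like(X_full)
    Hprev = np.empty_like(X_full)
    h = np.zeros(params.d)
    for i in range(n1):
        Hprev[i] = h
        h = A[i] * h + B[i] * X_full[i]
        H[i] = h
    Y = Gt * C * H
    _check_finite(Y, "recurrence outputs")
    local_pred, l_pre, l_act, l_N, l_xc, l_inv = _head_forward(
        Y[:n], p["lW1"], p["lb1"], p["lW2"], p["lb2"])
    global_pred, g_pre, g_act, g_N, g_xc, g_inv = _head_forward(
        Y[n:], p["gW1"], p["gb1"], p["gW2"], p["gb2"])
    cache = _ForwardCache()
    cache.X_full, cache.A_raw, cache.A, cache.B, cache.C, cache.Gt = X_full, A_raw, A, B, C, Gt
    cache.H, cache.Hprev, cache.Y = H, Hprev, Y
    cache.l_pre, cache.l_act, cache.l_N, cache.l_xc, cache.l_inv = l_pre, l_act, l_N, l_xc, l_inv
    cache.g_pre, cache.g_act, cache.g_N, cache.g_xc, cache.g_inv = g_pre, g_act, g_N, g_xc, g_inv
    out = SequenceOutput(
        local_outputs=Y[:n],
        global_output=Y[n],
        local_predictions=local_pred,
        global_prediction=global_pred[0],
    )
    return out, cache


def forward(X: np.ndarray, params: FusionParams) -> SequenceOutput:
    """Full forward pass for one slide: n patch embeddings -> n local
    predictions plus one global prediction."""
    out, _ = _forward_full(X, params)
    return out


def _mse(diff: np.ndarray, reduce: str) -> float:
    # diff is ... x G; squared error per item is mean (or sum) over genes
    per_item = (diff ** 2).mean(axis=-1) if reduce == "mean" else (diff ** 2).sum(axis=-1)
    return float(np.mean(per_item))


def loss_local(pred: np.ndarray, truth: np.ndarray, reduce: str = "mean") -> float:
    """Spot-level MSE: mean over spots of the per-spot squared error
    (averaged over genes by default)."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    return _mse(pred - truth, reduce)


def loss_global(pred: np.ndarray, truth: np.ndarray, reduce: str = "mean") -> float:
    """Bulk-level squared error of the single global prediction."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    return _mse(pred - truth, reduce)


def finetune_losses(local: float, global_: float, lam: float) -> tuple[float, float]:
    """Convex fine-tuning combinations of the local and global losses.

    loss_bulk = lam*local + (1-lam)*global;  loss_spot mirrors the weights.
    Their sum equals local + global for any lam in (0, 1).
    """
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lambda must lie in (0, 1), got {lam}")
    loss_bulk = lam * local + (1.0 - lam) * global_
    loss_spot = (1.0 - lam) * local + lam * global_
    return loss_bulk, loss_spot


def _head_backward(dOut, act, pre, N, xc, inv, W1, W2):
    dW2 = dOut.T @ act
    db2 = dOut.sum(axis=0)
    dact = dOut @ W2
    dpre = dact * _gelu_grad(pre)
    dW1 = dpre.T @ N
    db1 = dpre.sum(axis=0)
    dN = dpre @ W1
    dY = _layernorm_backward(dN, xc, inv)
    return dY, dW1, db1, dW2, db2


def forward_backward(
    X: np.ndarray,
    params: FusionParams,
    z_local: np.ndarray | None = None,
    z_global: np.ndarray | None = None,
    w_local: float = 1.0,
    w_global: float = 1.0,
) -> tuple[float, float, dict[str, np.ndarray]]:
    """Forward pass plus analytic gradients of
    ``w_local*loss_local + w_global*loss_global`` w.r.t. every parameter.

    Either target may be None (its term and weight are then ignored).
    Returns (local_loss, global_loss, grads); the unweighted per-term losses
    are reported so callers can log them independently of the mixing weights.
    """
    out, cc = _forward_full(X, params)
    p = params.params
    n = X.shape[0]
    reduce = params.loss_reduce
    gdiv = params.G if reduce == "mean" else 1

    ll = lg = 0.0
    dZl = np.zeros_like(out.local_predictions)
    dZg = np.zeros((1, params.G))
    if z_local is not None:
        z_local = np.asarray(z_local, float)
        diff = out.local_predictions - z_local
        ll = _mse(diff, reduce)
        dZl = w_local * 2.0 * diff / (n * gdiv)
    if z_global is not None:
        z_global = np.asarray(z_global, float)
        diffg = out.global_prediction - z_global
        lg = _mse(diffg, reduce)
        dZg = w_global * 2.0 * diffg[None, :] / gdiv

    grads = params.zeros_like()
    dY = np.zeros_like(cc.Y)
    if z_local is not None:
        dYl, dW1, db1, dW2, db2 = _head_backward(
            dZl, cc.l_act, cc.l_pre, cc.l_N, cc.l_xc, cc.l_inv,
            p["lW1"], p["lW2"])
        dY[:n] += dYl
        grads["lW1"] += dW1; grads["lb1"] += db1
        grads["lW2"] += dW2; grads["lb2"] += db2
    if z_global is not None:
        dYg, dW1, db1, dW2, db2 = _head_backward(
            dZg, cc.g_act, cc.g_pre, cc.g_N, cc.g_xc, cc.g_inv,
            p["gW1"], p["gW2"])
        dY[n:] += dYg
        grads["gW1"] += dW1; grads["gb1"] += db1
        grads["gW2"] += dW2; grads["gb2"] += db2

    # y = g*c*h
    dG = dY * cc.C * cc.H
    dC = dY * cc.Gt * cc.H
    dH_direct = dY * cc.Gt * cc.C

    # reverse scan through h_i = a_i h_{i-1} + b_i x_i
    n1 = n + 1
    dH = np.zeros_like(cc.H)
    carry = np.zeros(params.d)
    for i in range(n1 - 1, -1, -1):
        dh = dH_direct[i] + carry
        dH[i] = dh
        carry = dh * cc.A[i]
    dA = dH * cc.Hprev
    dB = dH * cc.X_full
    dX = dH * cc.B  # direct input-injection path

    if params.sigmoid_decay:
        dA_raw = dA * cc.A * (1.0 - cc.A)
    else:
        dA_raw = dA

    grads["W_a"] += dA_raw.T @ cc.X_full
    grads["b_a"] += dA_raw.sum(axis=0)
    grads["W_b"] += dB.T @ cc.X_full
    grads["b_b"] += dB.sum(axis=0)
    grads["W_c"] += dC.T @ cc.X_full
    grads["b_c"] += dC.sum(axis=0)
    grads["W_g"] += dG.T @ cc.X_full
    grads["b_g"] += dG.sum(axis=0)

    dX += dA_raw @ p["W_a"] + dB @ p["W_b"] + dC @ p["W_c"] + dG @ p["W_g"]
    grads["cls"] += dX[n]
    return ll, lg, grads
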