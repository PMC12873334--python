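"""The clipped GCN-LSTM forecaster: layers, loss, and parameter accounting.

The architecture, for one target drug and its k-hop subgraph of N drugs:

* symmetric normalisation of the self-looped adjacency,
  ``A_hat = D'^{-1/2} (M + I) D'^{-1/2}``;
* a stack of graph-convolution layers ``H <- ReLU(A_hat H W + b)`` mapping
  the F=16-dimensional per-snapshot node histories to 64-dimensional
  embeddings (two layers in the reference configuration);
* a *clip* that keeps only the target drug's row of the final embedding,
  discarding the other nodes' representations;
* a single-layer LSTM over the T_w=16 weekly snapshots;
* a bias-free dense head with ReLU producing the non-negative forecast.

Everything is plain NumPy. Gradients are computed by hand-written
backpropagation (see :class:`ForecastNetwork`); the simple per-sample
functions (:func:`gcn_layer_forward`, :func:`lstm_forward`, ...) are the
readable reference path and are tested against the batched network.

Parameter accounting matches the reference configuration exactly:
1088 (GCN layer 1) + 4160 (GCN layer 2) + 33,024 (LSTM) + 64 (head) = 38,336.
The LSTM carries recurrent weight matrices and a single bias vector per
gate — the configuration that reproduces the 33,024 count; zeroing the
recurrent matrices recovers the input-only gate equations as a special case.
The GCN layers carry biases (1088 = 16*64 + 64) while the head does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import scipy.special

__all__ = [
    "NormalizedGraph",
    "GcnParams",
    "LstmParams",
    "LstmState",
    "HeadParams",
    "ModelParams",
    "normalize_adjacency",
    "gcn_layer_forward",
    "clipped_gcn_forward",
    "lstm_forward",
    "predict_head",
    "mse_loss",
    "count_parameters",
    "init_model_params",
    "ForecastNetwork",
    "AdamOptimizer",
]

GATES = ("f", "i", "c", "o")


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return scipy.special.expit(x)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class NormalizedGraph:
    """Self-looped, symmetrically normalised adjacency."""

    self_looped_adjacency: np.ndarray  # M' = M + I
    degree: np.ndarray  # D' diagonal entries
    propagation_matrix: np.ndarray  # A_hat


@dataclass
class GcnParams:
    """Per-layer weight matrices and bias vectors of the GCN stack."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def layer0_weight(self) -> np.ndarray:
        return self.weights[0]

    @property
    def layer1_weight(self) -> np.ndarray:
        return self.weights[1]

    @property
    def n_layers(self) -> int:
        return len(self.weights)


@dataclass
class LstmParams:
    """Single-layer LSTM: input weights W_g, recurrent weights U_g and one
    bias b_g per gate g in (forget, input, candidate, output)."""

    W: dict[str, np.ndarray]
    U: dict[str, np.ndarray]
    b: dict[str, np.ndarray]

    @property
    def hidden_size(self) -> int:
        return self.b["f"].size

    @property
    def input_size(self) -> int:
        return self.W["f"].shape[0]


@dataclass
class LstmState:
    hidden: np.ndarray  # h_t
    cell: np.ndarray  # c_t
    forget_gate: np.ndarray | None = None
    input_gate: np.ndarray | None = None
    output_gate: np.ndarray | None = None
    candidate: np.ndarray | None = None


@dataclass
class HeadParams:
    """Bias-free dense regression head with ReLU; horizon tau = 1."""

    weight: np.ndarray  # (hidden,)
    horizon: int = 1


@dataclass
class ModelParams:
    gcn: GcnParams | None
    lstm: LstmParams | None
    head: HeadParams
    mlp: tuple[np.ndarray, np.ndarray] | None = None  # (W, b) for the MLP variant
    dropout_rate: float = 0.2


# ---------------------------------------------------------------------------
# reference (per-sample) operations


def normalize_adjacency(M: np.ndarray) -> NormalizedGraph:
    """``A_hat = D'^{-1/2} (M + I) D'^{-1/2}`` with D' the self-looped degrees.

    Self-loops guarantee degree >= 1, so the normalisation is always finite;
    the eigenvalues of ``A_hat`` lie in [-1, 1].
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"adjacency must be square, got {M.shape}")
    if not np.array_equal(M, M.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(M) != 0):
        raise ValueError("adjacency diagonal must be zero (self-loops are added here)")
    m_prime = M + np.eye(M.shape[0])
    degree = m_prime.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(degree)
    a_hat = m_prime * inv_sqrt[:, None] * inv_sqrt[None, :]
    return NormalizedGraph(self_looped_adjacency=m_prime, degree=degree, propagation_matrix=a_hat)


def gcn_layer_forward(
    normalized: NormalizedGraph,
    H: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    activation=relu,
) -> np.ndarray:
    """One propagation step ``activation(A_hat H W + b)``."""
    H = np.asarray(H, dtype=float)
    a_hat = normalized.propagation_matrix
    if a_hat.shape[1] != H.shape[0] or H.shape[1] != W.shape[0]:
        raise ValueError(f"shape mismatch: A_hat {a_hat.shape}, H {H.shape}, W {W.shape}")
    return activation(a_hat @ H @ W + b)


def clipped_gcn_forward(
    normalized: NormalizedGraph,
    snapshot_features: np.ndarray,
    params: GcnParams,
    target_position: int,
) -> np.ndarray:
    """Run the GCN stack on one snapshot and keep only the target's row.

    The clip discards all other drugs' embeddings so that the temporal model
    sees a single KG-contextualised representation of the target drug.
    """
    H = np.asarray(snapshot_features, dtype=float)
    if not 0 <= target_position < H.shape[0]:
        raise ValueError(f"target_position {target_position} out of range for N={H.shape[0]}")
    for W, b in zip(params.weights, params.biases):
        H = gcn_layer_forward(normalized, H, W, b)
    return H[target_position]


def lstm_forward(
    sequence: Iterable[np.ndarray],
    params: LstmParams,
    initial: LstmState | None = None,
) -> LstmState:
    """Iterate the gate equations over a sequence and return the final state.

    f_t = sigma(W_f x_t + U_f h_{t-1} + b_f)         (forget gate)
    i_t = sigma(W_i x_t + U_i h_{t-1} + b_i)         (input gate)
    C~_t = tanh(W_c x_t + U_c h_{t-1} + b_c)         (candidate state)
    c_t = f_t * c_{t-1} + i_t * C~_t                 (cell update)
    o_t = sigma(W_o x_t + U_o h_{t-1} + b_o)         (output gate)
    h_t = o_t * tanh(c_t)

    With the recurrent matrices U_g set to zero the gates depend on the
    input alone, the recurrence-free special case.
    """
    sequence = [np.asarray(x, dtype=float) for x in sequence]
    if not sequence:
        raise ValueError("empty input sequence")
    h = np.zeros(params.hidden_size) if initial is None else initial.hidden
    c = np.zeros(params.hidden_size) if initial is None else initial.cell
    state = LstmState(hidden=h, cell=c)
    for x in sequence:
        a = {g: params.W[g].T @ x + params.U[g].T @ h + params.b[g] for g in GATES}
        f, i, o = sigmoid(a["f"]), sigmoid(a["i"]), sigmoid(a["o"])
        chat = np.tanh(a["c"])
        c = f * c + i * chat
        h = o * np.tanh(c)
        state = LstmState(hidden=h, cell=c, forget_gate=f, input_gate=i, output_gate=o, candidate=chat)
    return state


def predict_head(state: LstmState, head: HeadParams) -> float:
    """``ReLU(h_t . w)`` — the non-negative one-step demand forecast."""
    if state.hidden.shape[-1] != head.weight.shape[0]:
        raise ValueError(
            f"hidden size {state.hidden.shape[-1]} != head weight size {head.weight.shape[0]}"
        )
    return float(max(state.hidden @ head.weight, 0.0))


def mse_loss(predictions: np.ndarray, truths: np.ndarray) -> float:
    """Mean squared error over all entries."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("empty prediction set")
    return float(np.mean((p - t) ** 2))


def count_parameters(model: ModelParams) -> dict[str, int]:
    """Trainable scalar count per block, plus the total.

    At the reference configuration (F=16, hidden 64, two GCN layers):
    gcn_layer_1 = 16*64 + 64 = 1088, gcn_layer_2 = 64*64 + 64 = 4160,
    lstm = 4*(64*64 + 64*64 + 64) = 33024, head = 64; total 38336.
    """
    counts: dict[str, int] = {}
    if model.gcn is not None:
        for l, (W, b) in enumerate(zip(model.gcn.weights, model.gcn.biases)):
            counts[f"gcn_layer_{l + 1}"] = W.size + b.size
    if model.lstm is not None:
        counts["lstm"] = sum(
            model.lstm.W[g].size + model.lstm.U[g].size + model.lstm.b[g].size for g in GATES
        )
    if model.mlp is not None:
        counts["mlp"] = model.mlp[0].size + model.mlp[1].size
    counts["head"] = model.head.weight.size
    counts["total"] = sum(v for k, v in counts.items() if k != "total")
    return counts


# ---------------------------------------------------------------------------
# initialisation


def _uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_model_params(
    rng: np.random.Generator,
    n_features: int = 16,
    gcn_layers: int = 2,
    gcn_hidden: int = 64,
    hidden_dim: int = 64,
    temporal: str = "lstm",
    dropout_rate: float = 0.2,
) -> ModelParams:
    """Fan-in uniform initialisation of every block.

    ``gcn_layers = 0`` omits the GCN (the temporal model then reads the raw
    window); ``temporal`` selects the LSTM or the one-hidden-layer MLP.
    """
    gcn = None
    temporal_in = n_features
    if gcn_layers > 0:
        dims = [n_features] + [gcn_hidden] * gcn_layers
        gcn = GcnParams(
            weights=[_uniform_fan_in(rng, (dims[l], dims[l + 1]), dims[l]) for l in range(gcn_layers)],
            biases=[_uniform_fan_in(rng, (dims[l + 1],), dims[l]) for l in range(gcn_layers)],
        )
        temporal_in = gcn_hidden
    lstm = None
    mlp = None
    if temporal == "lstm":
        lstm = LstmParams(
            W={g: _uniform_fan_in(rng, (temporal_in, hidden_dim), hidden_dim) for g in GATES},
            U={g: _uniform_fan_in(rng, (hidden_dim, hidden_dim), hidden_dim) for g in GATES},
            b={g: _uniform_fan_in(rng, (hidden_dim,), hidden_dim) for g in GATES},
        )
    elif temporal == "mlp":
        mlp = (
            _uniform_fan_in(rng, (temporal_in, hidden_dim), temporal_in),
            _uniform_fan_in(rng, (hidden_dim,), temporal_in),
        )
    else:
        raise ValueError(f"unknown temporal model {temporal!r}")
    head = HeadParams(weight=_uniform_fan_in(rng, (hidden_dim,), hidden_dim))
    return ModelParams(gcn=gcn, lstm=lstm, mlp=mlp, head=head, dropout_rate=dropout_rate)


# ---------------------------------------------------------------------------
# batched trainable network


class ForecastNetwork:
    """Batched forward/backward pass over (B, T_w, N, F) sample tensors.

    Configuration knobs mirror the ablation variants: number of GCN layers
    (0 = none), clip on/off with a pooling fallback, LSTM vs MLP temporal
    model. Dropout (inverted, training only) is applied to each GCN layer
    output and to the final temporal representation.
    """

    def __init__(
        self,
        params: ModelParams,
        *,
        clip: bool = True,
        pool: str = "mean",
    ) -> None:
        if pool not in ("mean", "sum"):
            raise ValueError("pool must be 'mean' or 'sum'")
        self.params = params
        self.clip = clip
        self.pool = pool

    # -- forward ----------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        a_hat: np.ndarray,
        target_position: int,
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Return predictions (B,) and the cache needed for backprop."""
        p = self.params
        drop = p.dropout_rate if train else 0.0
        if drop and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        cache: dict = {"gcn": [], "drop": []}
        H = np.asarray(X, dtype=float)  # (B, T, N, F)
        if p.gcn is not None:
            for W, b in zip(p.gcn.weights, p.gcn.biases):
                AH = np.matmul(a_hat, H)  # (B, T, N, d_in)
                pre = AH @ W + b
                H = relu(pre)
                mask = None
                if drop:
                    mask = (rng.random(H.shape) >= drop) / (1.0 - drop)
                    H = H * mask
                cache["gcn"].append({"AH": AH, "pre": pre, "mask": mask})
            if self.clip:
                Z = H[:, :, target_position, :]
            elif self.pool == "mean":
                Z = H.mean(axis=2)
            else:
                Z = H.sum(axis=2)
        else:
            Z = H[:, :, target_position, :]
        cache["Z_shape"] = Z.shape
        cache["n_nodes"] = X.shape[2]

        if p.lstm is not None:
            B, T, _ = Z.shape
            hid = p.lstm.hidden_size
            h = np.zeros((B, hid))
            c = np.zeros((B, hid))
            steps = []
            for t in range(T):
                x = Z[:, t, :]
                a = {g: x @ p.lstm.W[g] + h @ p.lstm.U[g] + p.lstm.b[g] for g in GATES}
                f, i, o = sigmoid(a["f"]), sigmoid(a["i"]), sigmoid(a["o"])
                chat = np.tanh(a["c"])
                c_new = f * c + i * chat
                h_new = o * np.tanh(c_new)
                steps.append({"x": x, "h_prev": h, "c_prev": c, "f": f, "i": i, "o": o, "chat": chat, "c": c_new})
                h, c = h_new, c_new
            cache["lstm"] = steps
            rep = h
        else:
            W_m, b_m = p.mlp
            x_last = Z[:, -1, :]
            pre_m = x_last @ W_m + b_m
            rep = relu(pre_m)
            cache["mlp"] = {"x": x_last, "pre": pre_m}
        mask = None
        if drop:
            mask = (rng.random(rep.shape) >= drop) / (1.0 - drop)
            rep = rep * mask
        cache["rep"] = rep
        cache["rep_mask"] = mask
        pre_y = rep @ p.head.weight
        cache["pre_y"] = pre_y
        return relu(pre_y), cache

    # -- backward ---------------------------------------------------------

    def backward(self, dy: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter, given dL/dyhat."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        d_pre_y = dy * (cache["pre_y"] > 0)
        grads["head_w"] = cache["rep"].T @ d_pre_y
        d_rep = np.outer(d_pre_y, p.head.weight)
        if cache["rep_mask"] is not None:
            d_rep = d_rep * cache["rep_mask"]

        B, T, d_in = cache["Z_shape"]
        dZ = np.zeros((B, T, d_in))
        if p.lstm is not None:
            hid = p.lstm.hidden_size
            for g in GATES:
                grads[f"lstm_W_{g}"] = np.zeros_like(p.lstm.W[g])
                grads[f"lstm_U_{g}"] = np.zeros_like(p.lstm.U[g])
                grads[f"lstm_b_{g}"] = np.zeros_like(p.lstm.b[g])
            dh = d_rep
            dc = np.zeros((B, hid))
            for t in range(T - 1, -1, -1):
                s = cache["lstm"][t]
                tanh_c = np.tanh(s["c"])
                do = dh * tanh_c
                dc = dc + dh * s["o"] * (1.0 - tanh_c**2)
                df = dc * s["c_prev"]
                di = dc * s["chat"]
                dchat = dc * s["i"]
                dc_prev = dc * s["f"]
                da = {
                    "f": df * s["f"] * (1.0 - s["f"]),
                    "i": di * s["i"] * (1.0 - s["i"]),
                    "o": do * s["o"] * (1.0 - s["o"]),
                    "c": dchat * (1.0 - s["chat"] ** 2),
                }
                dx = np.zeros((B, d_in))
                dh_prev = np.zeros((B, hid))
                for g in GATES:
                    grads[f"lstm_W_{g}"] += s["x"].T @ da[g]
                    grads[f"lstm_U_{g}"] += s["h_prev"].T @ da[g]
                    grads[f"lstm_b_{g}"] += da[g].sum(axis=0)
                    dx += da[g] @ p.lstm.W[g].T
                    dh_prev += da[g] @ p.lstm.U[g].T
                dZ[:, t, :] = dx
                dh, dc = dh_prev, dc_prev
        else:
            m = cache["mlp"]
            d_pre_m = d_rep * (m["pre"] > 0)
            grads["mlp_W"] = m["x"].T @ d_pre_m
            grads["mlp_b"] = d_pre_m.sum(axis=0)
            dZ[:, -1, :] = d_pre_m @ p.mlp[0].T

        if p.gcn is not None:
            N = cache["n_nodes"]
            dH = np.zeros((B, T, N, d_in))
            if self.clip:
                dH[:, :, cache["target_position"], :] = dZ
            elif self.pool == "mean":
                dH += dZ[:, :, None, :] / N
            else:
                dH += dZ[:, :, None, :]
            a_hat = cache["a_hat"]
            for l in range(len(p.gcn.weights) - 1, -1, -1):
                layer = cache["gcn"][l]
                if layer["mask"] is not None:
                    dH = dH * layer["mask"]
                dP = dH * (layer["pre"] > 0)
                grads[f"gcn_b_{l}"] = dP.sum(axis=(0, 1, 2))
                grads[f"gcn_W_{l}"] = np.einsum("btnf,btnd->fd", layer["AH"], dP)
                dAH = dP @ p.gcn.weights[l].T
                dH = np.matmul(a_hat, dAH)  # A_hat symmetric
        return grads

    # -- convenience ------------------------------------------------------

    def loss_and_grads(
        self,
        X: np.ndarray,
        y: np.ndarray,
        a_hat: np.ndarray,
        target_position: int,
        *,
        train: bool = True,
        rng: np.random.Generator | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        yhat, cache = self.forward(X, a_hat, target_position, train=train, rng=rng)
        cache["target_position"] = target_position
        cache["a_hat"] = a_hat
        loss = mse_loss(yhat, y)
        dy = 2.0 * (yhat - y) / y.size
        return loss, self.backward(dy, cache)

    def parameter_dict(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of every trainable block."""
        p = self.params
        out: dict[str, np.ndarray] = {}
        if p.gcn is not None:
            for l in range(len(p.gcn.weights)):
                out[f"gcn_W_{l}"] = p.gcn.weights[l]
                out[f"gcn_b_{l}"] = p.gcn.biases[l]
        if p.lstm is not None:
            for g in GATES:
                out[f"lstm_W_{g}"] = p.lstm.W[g]
                out[f"lstm_U_{g}"] = p.lstm.U[g]
                out[f"lstm_b_{g}"] = p.lstm.b[g]
        if p.mlp is not None:
            out["mlp_W"], out["mlp_b"] = p.mlp
        out["head_w"] = p.head.weight
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        current = self.parameter_dict()
        for name, arr in values.items():
            np.copyto(current[name], arr)


class AdamOptimizer:
    """Adam with bias correction; operates in place on a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
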