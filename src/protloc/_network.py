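"""NumPy implementation of the trainable network and its gradients.

Architecture (training mode "conv"):

    tokens -> embedding table -> 2 x [width-7 conv + ReLU]  -> H   (B, L, d)
    H -> s = H v -> Gaussian smooth -> softmax -> a               (B, L)
    z = sum_t a_t H_t                                             (B, d)
    z -> MLP head (1 hidden ReLU layer) -> sigmoid probabilities

In mode "fixed" the per-residue matrix H is supplied directly (one-hot or
precomputed embeddings) and only v and the heads receive gradients.

Losses:

- weighted focal loss, per label c with p_t = p_c if y_c = 1 else 1 - p_c:
      FL_c = -alpha_c (1 - p_t)^gamma log p_t
  averaged over labels, then over the batch;
- attention supervision: KL(q || a) with q uniform over the annotated signal
  residues, averaged over the sequences that carry an annotation.

All gradients are hand-derived; a finite-difference test guards them.
Batches are padded to the longest member and a validity mask keeps padding
out of every sum (convolution reads zeros beyond the boundary, and the
smoothing renormalizes over in-range taps only, matching the single-sequence
operators in :mod:`protloc.attention`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS_PROB = 1e-7
CONV_WIDTH = 7


# ---------------------------------------------------------------------------
# parameters

@dataclass
class Params:
    """All parameter groups; conv-encoder arrays are None in fixed mode."""

    W_emb: np.ndarray | None  # (A, d0)
    K1: np.ndarray | None     # (CONV_WIDTH * d0, d)
    b1: np.ndarray | None     # (d,)
    K2: np.ndarray | None     # (CONV_WIDTH * d, d)
    b2: np.ndarray | None     # (d,)
    v: np.ndarray             # (d,)
    heads: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    # heads[name] = {"W1": (d, h), "c1": (h,), "W2": (h, C), "c2": (C,)}

    def encoder_keys(self) -> list[str]:
        return [k for k in ("W_emb", "K1", "b1", "K2", "b2")
                if getattr(self, k) is not None]


def init_params(
    rng: np.random.Generator,
    d: int,
    hidden: int,
    n_loc: int,
    n_sig: int,
    mode: str,
    emb_dim: int = 32,
    alphabet_size: int = 21,
) -> Params:
    def dense(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    if mode == "conv":
        W_emb = rng.normal(0.0, 0.1, size=(alphabet_size, emb_dim))
        K1 = dense((CONV_WIDTH * emb_dim, d), CONV_WIDTH * emb_dim)
        b1 = np.zeros(d)
        K2 = dense((CONV_WIDTH * d, d), CONV_WIDTH * d)
        b2 = np.zeros(d)
    else:
        W_emb = K1 = b1 = K2 = b2 = None
    params = Params(
        W_emb=W_emb, K1=K1, b1=b1, K2=K2, b2=b2,
        v=rng.normal(0.0, 1.0 / np.sqrt(d), size=d),
    )
    for name, C in (("loc", n_loc), ("sig", n_sig)):
        params.heads[name] = {
            "W1": dense((d, hidden), d),
            "c1": np.zeros(hidden),
            "W2": dense((hidden, C), hidden),
            "c2": np.zeros(C),
        }
    return params


# ---------------------------------------------------------------------------
# primitive ops

def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, L, d) -> (B, L, CONV_WIDTH * d) windows with zero boundary."""
    B, L, d = x.shape
    half = CONV_WIDTH // 2
    xp = np.pad(x, ((0, 0), (half, half), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, CONV_WIDTH, axis=1)
    # win: (B, L, d, CONV_WIDTH) -> (B, L, CONV_WIDTH, d)
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
        B, L, CONV_WIDTH * d
    )


def _col2im(dcols: np.ndarray, d: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    B, L, _ = dcols.shape
    half = CONV_WIDTH // 2
    dw = dcols.reshape(B, L, CONV_WIDTH, d)
    dx = np.zeros((B, L + 2 * half, d))
    for k in range(CONV_WIDTH):
        dx[:, k : k + L] += dw[:, :, k]
    return dx[:, half : half + L]


def _corr1d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Batched symmetric correlation: out_t = sum_k w_k x_{t+k-half}."""
    B, L = x.shape
    half = w.shape[0] // 2
    xp = np.pad(x, ((0, 0), (half, half)))
    out = np.zeros_like(x)
    for k in range(w.shape[0]):
        out += w[k] * xp[:, k : k + L]
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# forward / backward

def forward(
    params: Params,
    kernel: np.ndarray,
    valid: np.ndarray,
    tokens: np.ndarray | None = None,
    H_fixed: np.ndarray | None = None,
    head: str = "loc",
) -> dict:
    """Run the network on one padded batch; returns a cache for backward.

    Exactly one of ``tokens`` (conv mode) or ``H_fixed`` (fixed mode) is
    given.  ``valid`` is the (B, L) 0/1 padding mask.
    """
    V = valid.astype(float)
    if tokens is not None:
        E = params.W_emb[tokens] * V[:, :, None]
        cols1 = _im2col(E)
        X1 = cols1 @ params.K1 + params.b1
        A1 = np.maximum(X1, 0.0) * V[:, :, None]
        cols2 = _im2col(A1)
        X2 = cols2 @ params.K2 + params.b2
        H = np.maximum(X2, 0.0) * V[:, :, None]
        cache = {"tokens": tokens, "E": E, "cols1": cols1, "X1": X1,
                 "A1": A1, "cols2": cols2, "X2": X2}
    else:
        H = H_fixed * V[:, :, None]
        cache = {}

    s = (H @ params.v) * V
    num = _corr1d(s * V, kernel)
    den = _corr1d(V, kernel)
    den = np.where(den > 0, den, 1.0)
    st = num / den

    neg = np.where(valid.astype(bool), st, -np.inf)
    m = neg.max(axis=1, keepdims=True)
    e = np.exp(neg - m)
    a = e / e.sum(axis=1, keepdims=True)

    z = np.einsum("bl,bld->bd", a, H)

    hp = params.heads[head]
    U_pre = z @ hp["W1"] + hp["c1"]
    U = np.maximum(U_pre, 0.0)
    logits = U @ hp["W2"] + hp["c2"]
    probs = _sigmoid(logits)

    cache.update(
        V=V, H=H, s=s, den=den, st=st, a=a, z=z,
        U_pre=U_pre, U=U, logits=logits, probs=probs,
        kernel=kernel, head=head,
    )
    return cache


def focal_loss_value_grad(
    probs: np.ndarray,
    targets: np.ndarray,
    alpha: np.ndarray,
    gamma: float,
    sample_weight: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean weighted focal loss and its gradient w.r.t. the logits.

    ``sample_weight`` (B,) selects/weights samples; weights are normalized by
    their sum so the value is a weighted mean over samples.
    """
    p = np.clip(probs, EPS_PROB, 1.0 - EPS_PROB)
    y = targets
    B, C = p.shape
    if sample_weight is None:
        sample_weight = np.ones(B)
    wsum = sample_weight.sum()
    if wsum == 0:
        return 0.0, np.zeros_like(p)

    p_t = np.where(y == 1, p, 1.0 - p)
    loss_mat = -alpha * (1.0 - p_t) ** gamma * np.log(p_t)
    loss = float((loss_mat.mean(axis=1) * sample_weight).sum() / wsum)

    log_pt = np.log(p_t)
    # d/dlogit of the per-label focal term (derived by chain rule through
    # the sigmoid; reduces to (p - y) when gamma = 0 and alpha = 1)
    grad_pos = alpha * (gamma * p * (1 - p) ** gamma * log_pt
                        - (1 - p) ** (gamma + 1))
    grad_neg = alpha * (-gamma * (1 - p) * p ** gamma * np.log(1 - p)
                        + p ** (gamma + 1))
    dlogits = np.where(y == 1, grad_pos, grad_neg)
    dlogits *= (sample_weight / wsum)[:, None] / C
    return loss, dlogits


def attention_kl_value_grad(
    a: np.ndarray, q: np.ndarray, has_mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean KL(q || a) over sequences with a mask, and its gradient w.r.t.
    the smoothed scores (the softmax inputs): d/dst = (a - q) / n_masked."""
    n = int(has_mask.sum())
    if n == 0:
        return 0.0, np.zeros_like(a)
    sel = has_mask.astype(bool)
    support = q[sel] > 0
    ratio = np.where(support, q[sel] / np.clip(a[sel], 1e-30, None), 1.0)
    kl = float(np.sum(q[sel] * np.log(ratio), where=support) / n)
    dst = np.zeros_like(a)
    dst[sel] = (a[sel] - q[sel]) / n
    return kl, dst


def backward(
    params: Params,
    cache: dict,
    dlogits: np.ndarray,
    dst_extra: np.ndarray | None = None,
    encoder_grads: bool = True,
) -> dict[str, np.ndarray | dict]:
    """Gradients of the scalar loss given d(loss)/d(logits) and an optional
    extra gradient w.r.t. the smoothed scores (attention supervision)."""
    V = cache["V"]
    H = cache["H"]
    a = cache["a"]
    head = cache["head"]
    hp = params.heads[head]
    grads: dict[str, np.ndarray | dict] = {}

    dU = dlogits @ hp["W2"].T
    dU_pre = dU * (cache["U_pre"] > 0)
    dz = dU_pre @ hp["W1"].T
    grads["heads"] = {
        head: {
            "W2": cache["U"].T @ dlogits,
            "c2": dlogits.sum(axis=0),
            "W1": cache["z"].T @ dU_pre,
            "c1": dU_pre.sum(axis=0),
        }
    }

    da = np.einsum("bd,bld->bl", dz, H)
    dH = a[:, :, None] * dz[:, None, :]

    # softmax backward (rows of `a` are zero at padding, so padded positions
    # contribute nothing)
    inner = (a * da).sum(axis=1, keepdims=True)
    dst = a * (da - inner)
    if dst_extra is not None:
        dst = dst + dst_extra

    ds = _corr1d(dst / cache["den"], cache["kernel"]) * V

    dH += ds[:, :, None] * params.v[None, None, :]
    grads["v"] = np.einsum("bl,bld->d", ds, H)

    if encoder_grads and cache.get("X2") is not None:
        dX2 = dH * (cache["X2"] > 0) * V[:, :, None]
        d = params.K2.shape[1]
        grads["K2"] = cache["cols2"].reshape(-1, params.K2.shape[0]).T @ \
            dX2.reshape(-1, d)
        grads["b2"] = dX2.sum(axis=(0, 1))
        dA1 = _col2im(dX2 @ params.K2.T, d) * V[:, :, None]
        dX1 = dA1 * (cache["X1"] > 0)
        grads["K1"] = cache["cols1"].reshape(-1, params.K1.shape[0]).T @ \
            dX1.reshape(-1, d)
        grads["b1"] = dX1.sum(axis=(0, 1))
        dE = _col2im(dX1 @ params.K1.T, params.W_emb.shape[1]) * V[:, :, None]
        dW_emb = np.zeros_like(params.W_emb)
        sel = V.astype(bool)
        np.add.at(dW_emb, cache["tokens"][sel], dE[sel])
        grads["W_emb"] = dW_emb
    return grads


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.s: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, tensors: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.s[key] = np.zeros_like(g)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.s[key] = self.beta2 * self.s[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / (1 - self.beta1 ** self.t)
            shat = self.s[key] / (1 - self.beta2 ** self.t)
            tensors[key] -= self.lr * mhat / (np.sqrt(shat) + self.eps)


def flatten_head_grads(grads: dict) -> dict[str, np.ndarray]:
    """Flatten the nested gradient dict to dotted keys for the optimizer."""
    flat: dict[str, np.ndarray] = {}
    for key, value in grads.items():
        if key == "heads":
            for head, hgrads in value.items():
                for name, g in hgrads.items():
                    flat[f"heads.{head}.{name}"] = g
        else:
            flat[key] = value
    return flat


def tensor_view(params: Params) -> dict[str, np.ndarray]:
    """Dotted-key view of all parameter arrays (shared memory)."""
    view: dict[str, np.ndarray] = {}
    for key in ("W_emb", "K1", "b1", "K2", "b2", "v"):
        arr = getattr(params, key)
        if arr is not None:
            view[key] = arr
    for head, hp in params.heads.items():
        for name, arr in hp.items():
            view[f"heads.{head}.{name}"] = arr
    return view
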