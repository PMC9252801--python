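"""Interpretable attention pooling over per-residue embeddings.

An L x d embedding matrix is collapsed to a single d-vector in four steps:

1. score:   s_t = v . h_t           (dot product with a learnable vector v)
2. smooth:  s~ = G * s              (5-tap Gaussian, sigma = 2 positions, so
                                     the support spans +-1 sigma; taps falling
                                     outside the sequence are dropped and the
                                     rest renormalized to sum 1)
3. weights: a = softmax(s~)         (numerically stable, max-subtracted)
4. pool:    z = sum_t a_t h_t

The smoothing encodes the prior that sorting signals occupy a contiguous run
of residues, so single-residue score spikes are discouraged.  The boundary
renormalization preserves constants: a constant score vector smooths to
itself, so smoothing never biases attention toward or away from the termini.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "gaussian_kernel",
    "score_tokens",
    "smooth_scores",
    "attention_weights",
    "pool",
    "AttentionProfile",
    "attention_profile",
]

KERNEL_WIDTH = 5
KERNEL_SIGMA = 2.0


def gaussian_kernel(width: int = KERNEL_WIDTH, sigma: float = KERNEL_SIGMA) -> np.ndarray:
    """Normalized Gaussian taps at integer offsets centred on 0.

    With the defaults, offsets -2..+2 with sigma 2 clip the Gaussian at one
    standard deviation.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("kernel width must be a positive odd integer")
    half = width // 2
    offsets = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-(offsets**2) / (2.0 * sigma**2))
    return w / w.sum()


def score_tokens(H: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Raw per-residue scores ``s_t = v . h_t`` for an (L, d) matrix."""
    H = np.asarray(H, dtype=float)
    v = np.asarray(v, dtype=float)
    if H.ndim != 2 or v.ndim != 1 or H.shape[1] != v.shape[0]:
        raise ValueError(
            f"dimension mismatch: H is {H.shape}, v is {v.shape}"
        )
    return H @ v


def smooth_scores(s: np.ndarray, kernel: np.ndarray | None = None) -> np.ndarray:
    """Gaussian-smooth a score vector with boundary renormalization.

    At position t the out-of-range taps are dropped and the remaining taps
    rescaled to sum 1, so the operator is linear, preserves constants, and
    commutes with sequence reversal (the kernel is symmetric).
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or s.shape[0] < 1:
        raise ValueError("scores must be a non-empty 1-D vector")
    if kernel is None:
        kernel = gaussian_kernel()
    half = kernel.shape[0] // 2
    padded = np.pad(s, half)
    ones = np.pad(np.ones_like(s), half)
    # correlate: num_t = sum_k w_k * s_{t+k}, den_t = kernel mass in range
    num = np.correlate(padded, kernel, mode="valid")
    den = np.correlate(ones, kernel, mode="valid")
    return num / den


def attention_weights(s_smooth: np.ndarray) -> np.ndarray:
    """Softmax of the smoothed scores (shift-invariant, sums to 1)."""
    s_smooth = np.asarray(s_smooth, dtype=float)
    if not np.all(np.isfinite(s_smooth)):
        raise ValueError("smoothed scores must be finite")
    shifted = s_smooth - s_smooth.max()
    e = np.exp(shifted)
    return e / e.sum()


def pool(H: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Attention-weighted sum of the residue representations: ``z = H^T a``."""
    H = np.asarray(H, dtype=float)
    a = np.asarray(a, dtype=float)
    if H.shape[0] != a.shape[0]:
        raise ValueError(f"length mismatch: H is {H.shape}, a is {a.shape}")
    return H.T @ a


@dataclass(frozen=True)
class AttentionProfile:
    """Raw, smoothed, and normalized attention over one sequence."""

    raw_scores: np.ndarray
    smoothed_scores: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        L = self.raw_scores.shape[0]
        if self.smoothed_scores.shape[0] != L or self.weights.shape[0] != L:
            raise ValueError("profile components must share one length")


def attention_profile(
    H: np.ndarray, v: np.ndarray, kernel: np.ndarray | None = None
) -> tuple[AttentionProfile, np.ndarray]:
    """Run all four pooling steps; returns the profile and the pooled vector."""
    s = score_tokens(H, v)
    st = smooth_scores(s, kernel)
    a = attention_weights(st)
    z = pool(H, a)
    return AttentionProfile(raw_scores=s, smoothed_scores=st, weights=a), z
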