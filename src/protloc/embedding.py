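"""Per-residue embedding providers behind one contract.

The localization model consumes an (L, d) real matrix per sequence and does
not care where it came from.  Three interchangeable providers are offered:

- ``onehot``: 21-dimensional indicator rows (20 residues + X);
- ``conv``: a small trainable encoder (residue embedding table followed by
  two width-7 convolutional ReLU layers), trained jointly with the
  classifier; the smallest encoder whose receptive field covers contiguous
  sorting-signal motifs;
- ``precomputed``: matrices computed elsewhere (e.g. by a protein language
  model) stored one ``.npy`` file per sequence next to a manifest CSV with
  columns id, L, d, file.

Sequences longer than ``max_length`` are truncated keeping both termini
(first ceil(max/2) and last floor(max/2) residues), because sorting signals
sit at the N- or C-terminus; signal masks must be truncated with the same
index map (:func:`truncation_indices`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _network
from .seq_io import ProteinRecord
from .vocab import AA_INDEX, ALPHABET

__all__ = [
    "EmbedderSpec",
    "truncation_indices",
    "tokenize",
    "OneHotEmbedder",
    "ConvEmbedder",
    "PrecomputedEmbedder",
    "get_embedder",
]

DEFAULT_MAX_LENGTH = 1022


@dataclass(frozen=True)
class EmbedderSpec:
    provider: str = "onehot"  # onehot | conv | precomputed
    d: int = len(ALPHABET)
    max_length: int = DEFAULT_MAX_LENGTH
    truncation_policy: str = "both-termini"

    def __post_init__(self) -> None:
        if self.provider not in ("onehot", "conv", "precomputed"):
            raise ValueError(f"unknown provider {self.provider!r}")
        if self.d < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.max_length < 41:
            raise ValueError("max_length must be >= 41")


def truncation_indices(L: int, max_length: int, policy: str = "both-termini") -> np.ndarray:
    """Indices of the residues kept after truncation (identity if L fits)."""
    if L <= max_length:
        return np.arange(L)
    if policy == "both-termini":
        head = (max_length + 1) // 2
        tail = max_length - head
        return np.concatenate([np.arange(head), np.arange(L - tail, L)])
    if policy == "n-terminal":
        return np.arange(max_length)
    raise ValueError(f"unknown truncation policy {policy!r}")


def tokenize(sequence: str) -> np.ndarray:
    return np.array([AA_INDEX[ch] for ch in sequence], dtype=np.int64)


class OneHotEmbedder:
    """Indicator-row embedding over the 21-letter alphabet."""

    d = len(ALPHABET)

    def __init__(self, max_length: int = DEFAULT_MAX_LENGTH,
                 truncation_policy: str = "both-termini"):
        self.max_length = max_length
        self.truncation_policy = truncation_policy

    def embed(self, record: ProteinRecord) -> np.ndarray:
        idx = truncation_indices(record.length, self.max_length,
                                 self.truncation_policy)
        tokens = tokenize(record.sequence)[idx]
        H = np.zeros((tokens.shape[0], self.d))
        H[np.arange(tokens.shape[0]), tokens] = 1.0
        return H


class ConvEmbedder:
    """Small trainable encoder: embedding table + two width-7 conv layers.

    Standalone use embeds with the current parameter values; inside the
    classifier the same arrays are updated by stage-1 training.
    """

    def __init__(self, d: int = 128, emb_dim: int = 32,
                 max_length: int = DEFAULT_MAX_LENGTH,
                 truncation_policy: str = "both-termini",
                 random_state: int = 0):
        self.d = d
        self.emb_dim = emb_dim
        self.max_length = max_length
        self.truncation_policy = truncation_policy
        rng = np.random.default_rng(random_state)
        p = _network.init_params(
            rng, d=d, hidden=1, n_loc=1, n_sig=1, mode="conv",
            emb_dim=emb_dim, alphabet_size=len(ALPHABET),
        )
        self.W_emb, self.K1, self.b1 = p.W_emb, p.K1, p.b1
        self.K2, self.b2 = p.K2, p.b2

    def embed(self, record: ProteinRecord) -> np.ndarray:
        idx = truncation_indices(record.length, self.max_length,
                                 self.truncation_policy)
        tokens = tokenize(record.sequence)[idx][None, :]
        E = self.W_emb[tokens]
        X1 = _network._im2col(E) @ self.K1 + self.b1
        A1 = np.maximum(X1, 0.0)
        X2 = _network._im2col(A1) @ self.K2 + self.b2
        return np.maximum(X2, 0.0)[0]


class PrecomputedEmbedder:
    """Lookup of per-sequence matrices stored as ``<dir>/<file>.npy`` plus a
    manifest CSV (id, L, d, file)."""

    def __init__(self, directory: str | Path,
                 max_length: int = DEFAULT_MAX_LENGTH,
                 truncation_policy: str = "both-termini"):
        self.directory = Path(directory)
        manifest = self.directory / "manifest.csv"
        if not manifest.exists():
            raise FileNotFoundError(f"no manifest.csv in {self.directory}")
        df = pd.read_csv(manifest)
        self._files = dict(zip(df["id"].astype(str), df["file"].astype(str)))
        dims = df["d"].unique()
        if len(dims) != 1:
            raise ValueError(f"inconsistent embedding dimensions: {dims}")
        self.d = int(dims[0])
        self.max_length = max_length
        self.truncation_policy = truncation_policy

    def embed(self, record: ProteinRecord) -> np.ndarray:
        if record.id not in self._files:
            raise KeyError(f"no precomputed embedding for id {record.id!r}")
        H = np.load(self.directory / self._files[record.id])
        if H.shape[0] != record.length:
            raise ValueError(
                f"stored matrix for {record.id!r} has {H.shape[0]} rows, "
                f"sequence has {record.length}"
            )
        if H.shape[1] != self.d:
            raise ValueError(
                f"stored matrix for {record.id!r} has d={H.shape[1]}, "
                f"manifest says {self.d}"
            )
        if not np.all(np.isfinite(H)):
            raise ValueError(f"non-finite entries in embedding for {record.id!r}")
        idx = truncation_indices(record.length, self.max_length,
                                 self.truncation_policy)
        return H[idx]

    @staticmethod
    def save(directory: str | Path, matrices: dict[str, np.ndarray]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for sid, H in matrices.items():
            fname = f"{sid}.npy"
            np.save(directory / fname, np.asarray(H, dtype=float))
            rows.append({"id": sid, "L": H.shape[0], "d": H.shape[1],
                         "file": fname})
        pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def get_embedder(spec: EmbedderSpec, directory: str | Path | None = None,
                 random_state: int = 0):
    if spec.provider == "onehot":
        return OneHotEmbedder(spec.max_length, spec.truncation_policy)
    if spec.provider == "conv":
        return ConvEmbedder(d=spec.d, max_length=spec.max_length,
                            truncation_policy=spec.truncation_policy,
                            random_state=random_state)
    if directory is None:
        raise ValueError("precomputed provider needs a directory")
    return PrecomputedEmbedder(directory, spec.max_length,
                               spec.truncation_policy)
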