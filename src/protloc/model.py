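"""Two-head multi-label model with interpretable attention, as an estimator.

:class:`ProteinSortingClassifier` follows the scikit-learn estimator
protocol: hyperparameters in ``__init__``, learned state in trailing-
underscore attributes set by :meth:`fit`, and ``get_params``/``set_params``
for composition with model selection tools.

Training is sequential, in two stages, because optimizing both tasks at once
is unstable:

- stage 1 trains the encoder (if trainable), the attention scoring vector v
  and the localization head, minimizing mean weighted focal loss over the
  localization labels plus ``lambda_attn`` times the attention-supervision
  loss KL(q || a) on sequences with annotated sorting-signal residues (q is
  uniform over the annotated residues);
- stage 2 freezes everything and trains only the signal-type head on the
  pooled representations of the sequences that carry signal-type annotation.

After both stages, per-label decision thresholds are fit on the training
split by maximizing MCC, and predictions use the inclusive >= rule with the
closest-label fallback so the decided set is never empty.

Focal-loss defaults: gamma = 2 (the canonical value of the loss it cites),
alpha = inverse label frequency normalized to mean 1 ("balanced").
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import f1_score

from . import _network
from .attention import AttentionProfile, gaussian_kernel
from .embedding import (
    DEFAULT_MAX_LENGTH,
    OneHotEmbedder,
    PrecomputedEmbedder,
    tokenize,
    truncation_indices,
)
from .metrics import ThresholdSet, decide, fit_thresholds
from .seq_io import LabeledSequence, ProteinRecord
from .vocab import ALPHABET, LOCALIZATION_CLASSES, SIGNAL_CLASSES

__all__ = [
    "LossConfig",
    "ProteinSortingClassifier",
    "focal_loss",
    "attention_supervision_loss",
    "train_stage1",
    "train_stage2",
    "fit_corpus",
]


@dataclass(frozen=True)
class LossConfig:
    gamma: float = 2.0
    alpha: np.ndarray | str = "balanced"
    lambda_attn: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.lambda_attn < 0:
            raise ValueError("lambda_attn must be >= 0")
        if not isinstance(self.alpha, str) and np.any(np.asarray(self.alpha) <= 0):
            raise ValueError("all alpha weights must be positive")


def focal_loss(probs: np.ndarray, targets: np.ndarray,
               gamma: float = 2.0, alpha: np.ndarray | float = 1.0) -> float:
    """Weighted focal loss, averaged over labels (and samples if batched)."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    targets = np.atleast_2d(np.asarray(targets))
    if probs.shape != targets.shape:
        raise ValueError("probability and target shapes differ")
    alpha_vec = np.broadcast_to(np.asarray(alpha, dtype=float), probs.shape[1:])
    value, _ = _network.focal_loss_value_grad(probs, targets, alpha_vec, gamma)
    return value


def attention_supervision_loss(weights: np.ndarray, mask: np.ndarray) -> float:
    """KL(q || a) with q uniform over the masked residues; 0 for empty mask."""
    mask = np.asarray(mask, dtype=float)
    if mask.sum() == 0:
        return 0.0
    q = mask / mask.sum()
    support = q > 0
    a = np.clip(np.asarray(weights, dtype=float), 1e-30, None)
    return float(np.sum(q[support] * np.log(q[support] / a[support])))


def _as_record(x) -> ProteinRecord:
    if isinstance(x, ProteinRecord):
        return x
    if isinstance(x, LabeledSequence):
        return x.record
    return ProteinRecord(id=str(abs(hash(x)) % 10**9), sequence=str(x))


class ProteinSortingClassifier(BaseEstimator):
    """Multi-label localization + sorting-signal classifier.

    Parameters
    ----------
    embedder : "conv", "onehot" or a PrecomputedEmbedder instance
        Per-residue representation provider.  "conv" is trained jointly in
        stage 1; the other two are fixed.
    conv_dim, emb_dim : int
        Channels of the trainable encoder and of its residue embedding table.
    hidden : int
        Width of the single hidden layer of each MLP head.
    gamma, alpha, lambda_attn :
        Focal-loss exponent, per-label weights ("balanced" = inverse
        frequency normalized to mean 1), and attention-supervision weight.
    lr, batch_size, max_epochs, patience :
        Adam learning rate, minibatch size, epoch cap, and early-stopping
        patience on validation micro-F1.
    max_length, truncation_policy :
        Long sequences are truncated keeping both termini by default.
    val_fraction : float
        Fraction held out for early stopping when no fold array is given.
    """

    def __init__(self, embedder="conv", conv_dim=128, emb_dim=32, hidden=256,
                 gamma=2.0, alpha="balanced", lambda_attn=1.0,
                 lr=1e-3, batch_size=64, max_epochs=100, patience=5,
                 max_length=DEFAULT_MAX_LENGTH,
                 truncation_policy="both-termini",
                 kernel_width=5, kernel_sigma=2.0,
                 val_fraction=0.1, random_state=0,
                 loc_classes=LOCALIZATION_CLASSES,
                 sig_classes=SIGNAL_CLASSES):
        self.embedder = embedder
        self.conv_dim = conv_dim
        self.emb_dim = emb_dim
        self.hidden = hidden
        self.gamma = gamma
        self.alpha = alpha
        self.lambda_attn = lambda_attn
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.max_length = max_length
        self.truncation_policy = truncation_policy
        self.kernel_width = kernel_width
        self.kernel_sigma = kernel_sigma
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.loc_classes = loc_classes
        self.sig_classes = sig_classes

    # ------------------------------------------------------------------ prep

    @property
    def _mode(self) -> str:
        return "conv" if self.embedder == "conv" else "fixed"

    def _prepare(self, X) -> list[dict]:
        """Tokenize / embed and truncate each input sequence."""
        items = []
        for x in X:
            rec = _as_record(x)
            idx = truncation_indices(rec.length, self.max_length,
                                     self.truncation_policy)
            item: dict = {"id": rec.id, "idx": idx, "L": idx.shape[0]}
            if self._mode == "conv":
                item["tokens"] = tokenize(rec.sequence)[idx]
            elif self.embedder == "onehot":
                item["H"] = OneHotEmbedder(
                    self.max_length, self.truncation_policy).embed(rec)
            else:
                item["H"] = self.embedder.embed(rec)
            items.append(item)
        return items

    def _fixed_dim(self, items) -> int:
        if self.embedder == "onehot":
            return len(ALPHABET)
        if isinstance(self.embedder, PrecomputedEmbedder):
            return self.embedder.d
        return items[0]["H"].shape[1]

    def _batch(self, items: Sequence[dict], masks=None):
        """Pad a list of prepared items into batch arrays."""
        B = len(items)
        Lmax = max(it["L"] for it in items)
        valid = np.zeros((B, Lmax))
        for i, it in enumerate(items):
            valid[i, : it["L"]] = 1.0
        out = {"valid": valid}
        if self._mode == "conv":
            tokens = np.zeros((B, Lmax), dtype=np.int64)
            for i, it in enumerate(items):
                tokens[i, : it["L"]] = it["tokens"]
            out["tokens"] = tokens
        else:
            d = items[0]["H"].shape[1]
            H = np.zeros((B, Lmax, d))
            for i, it in enumerate(items):
                H[i, : it["L"]] = it["H"]
            out["H_fixed"] = H
        if masks is not None:
            q = np.zeros((B, Lmax))
            has = np.zeros(B, dtype=bool)
            for i, m in enumerate(masks):
                if m is not None and m.sum() > 0:
                    q[i, : m.shape[0]] = m / m.sum()
                    has[i] = True
            out["q"] = q
            out["has_mask"] = has
        return out

    def _alpha_vec(self, Y: np.ndarray) -> np.ndarray:
        if isinstance(self.alpha, str):
            if self.alpha != "balanced":
                raise ValueError(f"unknown alpha policy {self.alpha!r}")
            freq = np.clip(Y.mean(axis=0), 1.0 / max(len(Y), 1), None)
            w = 1.0 / freq
            return w / w.mean()
        return np.broadcast_to(
            np.asarray(self.alpha, dtype=float), (Y.shape[1],)
        ).copy()

    def _split(self, n: int, folds, val_fold, rng) -> np.ndarray:
        if folds is not None:
            folds = np.asarray(folds)
            if val_fold is None:
                val_fold = int(folds.max())
            return folds == val_fold
        val = np.zeros(n, dtype=bool)
        k = max(1, int(round(self.val_fraction * n)))
        val[rng.permutation(n)[:k]] = True
        return val

    # ------------------------------------------------------------------ fit

    def fit(self, X, y, *, signal_types=None, signal_masks=None,
            folds=None, val_fold=None):
        """Run stage 1, stage 2 (when signal-type targets are given), and
        threshold fitting.  ``signal_masks`` is a list of per-residue 0/1
        arrays (or None); ``signal_types`` an (n, C_sig) binary matrix whose
        all-zero rows without a mask count as unannotated only if
        ``signal_types`` is None for that row (use np.nan rows to mark
        unannotated sequences)."""
        self.fit_stage1(X, y, signal_masks=signal_masks, folds=folds,
                        val_fold=val_fold)
        if signal_types is not None:
            self.fit_stage2(signal_types)
        return self

    def fit_stage1(self, X, y, *, signal_masks=None, folds=None,
                   val_fold=None):
        y = np.asarray(y, dtype=int)
        if y.ndim != 2 or y.shape[1] != len(self.loc_classes):
            raise ValueError(
                f"y must be (n, {len(self.loc_classes)}); got {y.shape}"
            )
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        if y.sum() == 0:
            raise ValueError("no positive localization labels in training data")
        rng = np.random.default_rng(self.random_state)
        items = self._prepare(X)
        n = len(items)

        masks = [None] * n
        if signal_masks is not None:
            for i, m in enumerate(signal_masks):
                if m is not None:
                    m = np.asarray(m, dtype=float)[items[i]["idx"]]
                    masks[i] = m

        val = self._split(n, folds, val_fold, rng)
        train_idx = np.flatnonzero(~val)
        val_idx = np.flatnonzero(val)
        if train_idx.size == 0 or val_idx.size == 0:
            raise ValueError("training and validation splits must be non-empty")

        d = self.conv_dim if self._mode == "conv" else self._fixed_dim(items)
        params = _network.init_params(
            rng, d=d, hidden=self.hidden, n_loc=len(self.loc_classes),
            n_sig=len(self.sig_classes), mode=self._mode,
            emb_dim=self.emb_dim, alphabet_size=len(ALPHABET),
        )
        kernel = gaussian_kernel(self.kernel_width, self.kernel_sigma)
        alpha_loc = self._alpha_vec(y[train_idx])

        trainable = [k for k in _network.tensor_view(params)
                     if not k.startswith("heads.sig.")]
        opt = _network.Adam(lr=self.lr)
        best = {"metric": -np.inf, "params": None, "epoch": -1}
        history = []
        stall = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(train_idx)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, order.size, self.batch_size):
                idx = order[start : start + self.batch_size]
                batch = self._batch([items[i] for i in idx],
                                    masks=[masks[i] for i in idx])
                cache = _network.forward(
                    params, kernel, batch["valid"],
                    tokens=batch.get("tokens"),
                    H_fixed=batch.get("H_fixed"), head="loc",
                )
                loss, dlogits = _network.focal_loss_value_grad(
                    cache["probs"], y[idx], alpha_loc, self.gamma
                )
                dst_extra = None
                if self.lambda_attn > 0:
                    kl, dst = _network.attention_kl_value_grad(
                        cache["a"], batch["q"], batch["has_mask"]
                    )
                    loss += self.lambda_attn * kl
                    dst_extra = self.lambda_attn * dst
                grads = _network.backward(
                    params, cache, dlogits, dst_extra=dst_extra,
                    encoder_grads=(self._mode == "conv"),
                )
                flat = _network.flatten_head_grads(grads)
                flat = {k: g for k, g in flat.items() if k in trainable}
                opt.step(_network.tensor_view(params), flat)
                epoch_loss += loss
                n_batches += 1
            val_probs = self._forward_probs(params, kernel,
                                            [items[i] for i in val_idx], "loc")
            metric = f1_score(y[val_idx], (val_probs >= 0.5).astype(int),
                              average="micro", zero_division=0)
            history.append({"epoch": epoch,
                            "train_loss": epoch_loss / max(n_batches, 1),
                            "val_micro_f1": float(metric)})
            if metric > best["metric"] + 1e-6:
                best = {"metric": metric,
                        "params": copy.deepcopy(params), "epoch": epoch}
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.params_ = best["params"] if best["params"] is not None else params
        self.kernel_ = kernel
        self.items_train_cache_ = None
        self.history_ = history
        self.stage_ = "stage1"
        self.alpha_loc_ = alpha_loc
        self._train_items = items
        self._train_masks = masks
        self._train_val = val
        self._train_y = y
        # thresholds for the localization task, on the training split
        train_probs = self._forward_probs(
            self.params_, kernel, [items[i] for i in train_idx], "loc")
        self.thresholds_loc_ = fit_thresholds(train_probs, y[train_idx])
        return self

    def fit_stage2(self, signal_types):
        """Train the signal-type head on frozen pooled representations.

        ``signal_types``: (n, C_sig) array aligned with the stage-1 inputs;
        rows containing NaN are treated as unannotated and excluded."""
        if getattr(self, "stage_", None) != "stage1":
            raise RuntimeError("fit_stage2 requires a completed stage 1")
        sig = np.asarray(signal_types, dtype=float)
        if sig.shape != (len(self._train_items), len(self.sig_classes)):
            raise ValueError(
                f"signal_types must be (n, {len(self.sig_classes)})"
            )
        annotated = ~np.isnan(sig).any(axis=1)
        if annotated.sum() == 0:
            raise ValueError("no sequences with signal-type annotation")
        rng = np.random.default_rng(self.random_state + 1)

        Z = self._forward_pooled(self.params_, self.kernel_, self._train_items)
        train_sel = annotated & ~self._train_val
        val_sel = annotated & self._train_val
        if val_sel.sum() == 0:  # fall back to a slice of the training part
            ids = np.flatnonzero(train_sel)
            val_ids = ids[rng.permutation(ids.size)[: max(1, ids.size // 10)]]
            val_sel = np.zeros_like(train_sel)
            val_sel[val_ids] = True
            train_sel = train_sel & ~val_sel
        Y = np.nan_to_num(sig).astype(int)
        alpha_sig = self._alpha_vec(Y[train_sel])
        self.alpha_sig_ = alpha_sig

        hp = self.params_.heads["sig"]
        opt = _network.Adam(lr=self.lr)
        best = {"metric": -np.inf, "head": None}
        stall = 0
        train_ids = np.flatnonzero(train_sel)
        for epoch in range(self.max_epochs):
            order = rng.permutation(train_ids)
            for start in range(0, order.size, self.batch_size):
                idx = order[start : start + self.batch_size]
                z = Z[idx]
                u_pre = z @ hp["W1"] + hp["c1"]
                u = np.maximum(u_pre, 0.0)
                logits = u @ hp["W2"] + hp["c2"]
                probs = _network._sigmoid(logits)
                _, dlogits = _network.focal_loss_value_grad(
                    probs, Y[idx], alpha_sig, self.gamma
                )
                dU = (dlogits @ hp["W2"].T) * (u_pre > 0)
                grads = {
                    "W2": u.T @ dlogits, "c2": dlogits.sum(axis=0),
                    "W1": z.T @ dU, "c1": dU.sum(axis=0),
                }
                opt.step(hp, grads)
            val_probs = self._head_probs(Z[val_sel], hp)
            metric = f1_score(Y[val_sel], (val_probs >= 0.5).astype(int),
                              average="micro", zero_division=0)
            if metric > best["metric"] + 1e-6:
                best = {"metric": metric,
                        "head": {k: a.copy() for k, a in hp.items()}}
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best["head"] is not None:
            for k in hp:
                hp[k][...] = best["head"][k]
        self.stage_ = "stage2"
        train_probs = self._head_probs(Z[train_sel], hp)
        self.thresholds_sig_ = fit_thresholds(train_probs, Y[train_sel])
        return self

    # ------------------------------------------------------------- inference

    @staticmethod
    def _head_probs(Z: np.ndarray, hp: dict[str, np.ndarray]) -> np.ndarray:
        u = np.maximum(Z @ hp["W1"] + hp["c1"], 0.0)
        return _network._sigmoid(u @ hp["W2"] + hp["c2"])

    def _forward_batches(self, params, kernel, items, head):
        for start in range(0, len(items), self.batch_size):
            chunk = items[start : start + self.batch_size]
            batch = self._batch(chunk)
            cache = _network.forward(
                params, kernel, batch["valid"],
                tokens=batch.get("tokens"),
                H_fixed=batch.get("H_fixed"), head=head,
            )
            yield chunk, cache

    def _forward_probs(self, params, kernel, items, head) -> np.ndarray:
        out = []
        for _, cache in self._forward_batches(params, kernel, items, head):
            out.append(cache["probs"])
        return np.concatenate(out, axis=0)

    def _forward_pooled(self, params, kernel, items) -> np.ndarray:
        out = []
        for _, cache in self._forward_batches(params, kernel, items, "loc"):
            out.append(cache["z"])
        return np.concatenate(out, axis=0)

    def _check_fitted(self, stage: str = "stage1") -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        if stage == "stage2" and self.stage_ != "stage2":
            raise RuntimeError("signal head not trained (run fit_stage2)")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self._forward_probs(self.params_, self.kernel_,
                                   self._prepare(X), "loc")

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        probs = self.predict_proba(X)
        preds = decide(probs, self.thresholds_loc_)
        return np.stack([p.decided for p in preds])

    def predict_signal_proba(self, X) -> np.ndarray:
        self._check_fitted("stage2")
        Z = self._forward_pooled(self.params_, self.kernel_, self._prepare(X))
        return self._head_probs(Z, self.params_.heads["sig"])

    def predict_signal(self, X) -> np.ndarray:
        probs = self.predict_signal_proba(X)
        preds = decide(probs, self.thresholds_sig_)
        return np.stack([p.decided for p in preds])

    def attention_profiles(self, X) -> list[AttentionProfile]:
        self._check_fitted()
        profiles = []
        for chunk, cache in self._forward_batches(
            self.params_, self.kernel_, self._prepare(X), "loc"
        ):
            for i, it in enumerate(chunk):
                L = it["L"]
                profiles.append(AttentionProfile(
                    raw_scores=cache["s"][i, :L].copy(),
                    smoothed_scores=cache["st"][i, :L].copy(),
                    weights=cache["a"][i, :L].copy(),
                ))
        return profiles

    def forward_one(self, record: ProteinRecord):
        """Localization probabilities, signal probabilities (or None before
        stage 2), and the attention profile for one sequence."""
        self._check_fitted()
        loc = self.predict_proba([record])[0]
        sig = None
        if getattr(self, "stage_", None) == "stage2":
            sig = self.predict_signal_proba([record])[0]
        profile = self.attention_profiles([record])[0]
        return loc, sig, profile

    # ------------------------------------------------------------ persistence

    def save(self, path: str | Path) -> None:
        self._check_fitted()
        path = Path(path)
        arrays = {k.replace(".", "__"): a
                  for k, a in _network.tensor_view(self.params_).items()}
        arrays["kernel"] = self.kernel_
        arrays["thresholds_loc"] = self.thresholds_loc_.tau
        if getattr(self, "stage_", None) == "stage2":
            arrays["thresholds_sig"] = self.thresholds_sig_.tau
        meta = {k: v for k, v in self.get_params().items()
                if isinstance(v, (int, float, str, bool, tuple, list, type(None)))}
        meta["loc_classes"] = list(self.loc_classes)
        meta["sig_classes"] = list(self.sig_classes)
        meta["stage"] = self.stage_
        np.savez(path, **arrays)
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ProteinSortingClassifier":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        stage = meta.pop("stage")
        meta["loc_classes"] = tuple(meta["loc_classes"])
        meta["sig_classes"] = tuple(meta["sig_classes"])
        est = cls(**{k: v for k, v in meta.items()
                     if k in cls().get_params()})
        data = np.load(path)
        params = _network.Params(W_emb=None, K1=None, b1=None, K2=None,
                                 b2=None, v=None)
        heads: dict[str, dict[str, np.ndarray]] = {}
        for key in data.files:
            if key.startswith("heads__"):
                _, head, name = key.split("__")
                heads.setdefault(head, {})[name] = data[key]
            elif key in ("W_emb", "K1", "b1", "K2", "b2", "v"):
                setattr(params, key, data[key])
        params.heads = heads
        est.params_ = params
        est.kernel_ = data["kernel"]
        est.thresholds_loc_ = ThresholdSet(tau=data["thresholds_loc"])
        if "thresholds_sig" in data.files:
            est.thresholds_sig_ = ThresholdSet(tau=data["thresholds_sig"])
        est.stage_ = stage
        est.history_ = []
        return est


# ---------------------------------------------------------------- wrappers

def _corpus_arrays(data: Sequence[LabeledSequence], loc_classes, sig_classes):
    y = np.zeros((len(data), len(loc_classes)), dtype=int)
    sig = np.full((len(data), len(sig_classes)), np.nan)
    masks: list[np.ndarray | None] = []
    for i, ls in enumerate(data):
        for lab in ls.localization.labels:
            y[i, loc_classes.index(lab)] = 1
        if ls.signal is not None:
            sig[i] = 0.0
            for t in ls.signal.types:
                sig[i, sig_classes.index(t)] = 1.0
            masks.append(ls.signal.mask.astype(float))
        else:
            masks.append(None)
    return y, sig, masks


def fit_corpus(data: Sequence[LabeledSequence],
               estimator: ProteinSortingClassifier | None = None,
               val_fold: int | None = None) -> ProteinSortingClassifier:
    """Fit an estimator directly from labelled sequences, using their
    ``partition`` fields (if present) for the early-stopping split."""
    est = estimator or ProteinSortingClassifier()
    loc_classes = list(est.loc_classes)
    sig_classes = list(est.sig_classes)
    y, sig, masks = _corpus_arrays(data, loc_classes, sig_classes)
    folds = None
    if all(ls.partition is not None for ls in data):
        folds = np.array([ls.partition for ls in data])
    X = [ls.record for ls in data]
    est.fit(X, y, signal_types=sig if not np.isnan(sig).all() else None,
            signal_masks=masks, folds=folds, val_fold=val_fold)
    return est


def train_stage1(data: Sequence[LabeledSequence], cfg: LossConfig | None = None,
                 seed: int = 0, **kwargs) -> ProteinSortingClassifier:
    """Stage-1 training on a labelled corpus; returns the estimator."""
    cfg = cfg or LossConfig()
    est = ProteinSortingClassifier(
        gamma=cfg.gamma, alpha=cfg.alpha, lambda_attn=cfg.lambda_attn,
        random_state=seed, **kwargs,
    )
    y, _, masks = _corpus_arrays(data, list(est.loc_classes),
                                 list(est.sig_classes))
    folds = None
    if all(ls.partition is not None for ls in data):
        folds = np.array([ls.partition for ls in data])
    est.fit_stage1([ls.record for ls in data], y, signal_masks=masks,
                   folds=folds)
    return est


def train_stage2(estimator: ProteinSortingClassifier,
                 data: Sequence[LabeledSequence]) -> ProteinSortingClassifier:
    """Stage-2 training of the signal head; stage 1 must be complete."""
    _, sig, _ = _corpus_arrays(data, list(estimator.loc_classes),
                               list(estimator.sig_classes))
    estimator.fit_stage2(sig)
    return estimator
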