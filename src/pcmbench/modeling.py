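"""PCM classifier (CNN protein branch + FFN fingerprint branch) and the
imbalance-aware random baseline.

The baseline makes input-naive predictions that reproduce the training
balance per protein: with ``f`` the fraction of actives in the training
samples involving a protein and ``n`` the number of its test samples,
exactly ``floor(f*n + 0.5)`` scores are drawn uniformly from [0.5, 1]
(actives) and the rest from [0, 0.5) (inactives), concatenated and
shuffled.  Binarizing at 0.5 therefore recovers the training balance for
every single draw, not merely in expectation.

The deep model mirrors a standard two-branch proteochemometric
architecture: a 1-D convolution with ReLU and global max pooling over the
1499 x 26 one-hot protein matrix, a dense ReLU layer over the 881-bit
fingerprint, dropout in both branches, and a sigmoid unit on the merged
representation.  It is implemented directly on numpy arrays (forward and
backward passes written out; Adam optimizer) and trained with binary
cross-entropy; the selected weights are those of the epoch with maximum
validation accuracy, earliest epoch on ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from pcmbench.core_data import (
    FINGERPRINT_LENGTH,
    MAX_SEQUENCE_LENGTH,
    N_CHANNELS,
    BioactivityRecord,
    encode_protein,
)
from pcmbench.seeding import rng_for

logger = logging.getLogger(__name__)


def random_baseline(f: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Imbalance-aware random prediction scores for one protein's test set."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must be in [0, 1], got {f}")
    if n < 0:
        raise ValueError("n must be >= 0")
    n_active = int(np.floor(f * n + 0.5))
    scores = np.concatenate(
        [
            0.5 + 0.5 * rng.random(n_active),  # [0.5, 1]
            0.5 * rng.random(n - n_active),  # [0, 0.5)
        ]
    )
    rng.shuffle(scores)
    return scores


@dataclass
class ModelConfig:
    conv_filters: int = 32
    conv_kernel: int = 8
    dense_size: int = 64
    dropout_rate: float = 0.25
    learning_rate: float = 5e-4
    adam_beta1: float = 0.9  # the conventional values; see docs/methods.md
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    adam_decay: float | None = None  # None -> learning_rate / epochs
    epochs: int = 100
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.conv_kernel > MAX_SEQUENCE_LENGTH:
            raise ValueError("conv kernel longer than the protein encoding")


class PCMNetwork:
    """Two-branch network on (protein one-hot, fingerprint) pairs."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = rng_for(config.seed, "init")
        K, C, F = config.conv_kernel, N_CHANNELS, config.conv_filters
        D = config.dense_size
        # He initialization for the ReLU layers, Glorot for the output
        self.params = {
            "Wc": (rng.standard_normal((K * C, F)) * np.sqrt(2.0 / (K * C))),
            "bc": np.zeros(F),
            "W1": (rng.standard_normal((FINGERPRINT_LENGTH, D))
                   * np.sqrt(2.0 / FINGERPRINT_LENGTH)),
            "b1": np.zeros(D),
            "W2": (rng.standard_normal((F + D, 1)) * np.sqrt(1.0 / (F + D))),
            "b2": np.zeros(1),
        }
        self.params = {k: v.astype(np.float64) for k, v in self.params.items()}
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- forward ---------------------------------------------------------
    def _windows(self, Xp: np.ndarray) -> np.ndarray:
        """(B, T', K*C) sliding windows of the protein matrix."""
        K = self.config.conv_kernel
        w = np.lib.stride_tricks.sliding_window_view(Xp, K, axis=1)  # B,T',C,K
        w = np.swapaxes(w, 2, 3)  # B, T', K, C
        B, Tp = w.shape[0], w.shape[1]
        return np.ascontiguousarray(w).reshape(B, Tp, K * N_CHANNELS)

    def forward(
        self,
        Xp: np.ndarray,
        Xf: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Probabilities for a batch; returns (scores, cache for backward)."""
        p = self.params
        win = self._windows(Xp.astype(np.float64))
        conv = win @ p["Wc"] + p["bc"]  # B, T', F
        conv_relu = np.maximum(conv, 0.0)
        t_star = conv_relu.argmax(axis=1)  # B, F
        pooled = np.take_along_axis(conv_relu, t_star[:, None, :], axis=1)[:, 0, :]
        dense = Xf.astype(np.float64) @ p["W1"] + p["b1"]
        dense_relu = np.maximum(dense, 0.0)
        cache: dict = {"win": win, "t_star": t_star, "Xf": Xf, "dense": dense}
        if train and self.config.dropout_rate > 0.0:
            keep = 1.0 - self.config.dropout_rate
            mask_p = (rng.random(pooled.shape) < keep) / keep
            mask_f = (rng.random(dense_relu.shape) < keep) / keep
            pooled = pooled * mask_p
            dense_relu = dense_relu * mask_f
            cache["mask_p"], cache["mask_f"] = mask_p, mask_f
        merged = np.concatenate([pooled, dense_relu], axis=1)
        logit = merged @ p["W2"] + p["b2"]
        prob = 1.0 / (1.0 + np.exp(-logit[:, 0]))
        cache["merged"] = merged
        return prob, cache

    def predict_scores(self, Xp: np.ndarray, Xf: np.ndarray) -> np.ndarray:
        """Deterministic inference (dropout disabled)."""
        prob, _ = self.forward(Xp, Xf, train=False)
        return prob

    # -- backward + Adam -------------------------------------------------
    def _backward(self, prob: np.ndarray, y: np.ndarray, cache: dict) -> dict:
        p = self.params
        B = len(y)
        F = self.config.conv_filters
        dlogit = (prob - y)[:, None] / B  # BCE + sigmoid
        grads = {
            "W2": cache["merged"].T @ dlogit,
            "b2": dlogit.sum(axis=0),
        }
        dmerged = dlogit @ p["W2"].T
        dpooled, ddense_relu = dmerged[:, :F], dmerged[:, F:]
        if "mask_p" in cache:
            dpooled = dpooled * cache["mask_p"]
            ddense_relu = ddense_relu * cache["mask_f"]
        ddense = ddense_relu * (cache["dense"] > 0)
        grads["W1"] = cache["Xf"].astype(np.float64).T @ ddense
        grads["b1"] = ddense.sum(axis=0)
        # scatter pooled gradient back to the argmax positions
        win = cache["win"]
        dconv = np.zeros((win.shape[0], win.shape[1], F))
        np.put_along_axis(dconv, cache["t_star"][:, None, :], dpooled[:, None, :], axis=1)
        grads["Wc"] = np.einsum("btk,btf->kf", win, dconv)
        grads["bc"] = dconv.sum(axis=(0, 1))
        return grads

    def _adam_step(self, grads: dict) -> None:
        cfg = self.config
        self._adam_t += 1
        t = self._adam_t
        decay = (
            cfg.adam_decay
            if cfg.adam_decay is not None
            else cfg.learning_rate / cfg.epochs
        )
        lr = cfg.learning_rate / (1.0 + decay * t)  # inverse-time decay
        for k, g in grads.items():
            m = self._adam_m[k] = cfg.adam_beta1 * self._adam_m[k] + (1 - cfg.adam_beta1) * g
            v = self._adam_v[k] = cfg.adam_beta2 * self._adam_v[k] + (1 - cfg.adam_beta2) * g**2
            mhat = m / (1 - cfg.adam_beta1**t)
            vhat = v / (1 - cfg.adam_beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + cfg.adam_epsilon)

    def get_weights(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict) -> None:
        self.params = {k: v.copy() for k, v in weights.items()}


def build_model(config: ModelConfig) -> PCMNetwork:
    """An untrained two-branch PCM classifier; logs its parameter count."""
    model = PCMNetwork(config)
    logger.info("built PCM network with %d parameters", model.n_parameters)
    return model


def encode_batch(
    records: list[BioactivityRecord],
    fingerprints: dict[str, np.ndarray],
    sequences: dict[str, str],
    protein_cache: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(protein one-hot stack, fingerprint stack, label vector) for records."""
    if protein_cache is None:
        protein_cache = {}
    for rec in records:
        if rec.protein_id not in protein_cache:
            protein_cache[rec.protein_id] = encode_protein(sequences[rec.protein_id])
    Xp = np.stack([protein_cache[r.protein_id] for r in records]).astype(np.float32)
    Xf = np.stack([fingerprints[r.compound_id] for r in records]).astype(np.float32)
    y = np.array([r.label for r in records], dtype=np.float64)
    return Xp, Xf, y


def train_select(
    model: PCMNetwork,
    train: tuple[np.ndarray, np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: ModelConfig | None = None,
) -> tuple[PCMNetwork, int, list[dict]]:
    """Train with Adam and return the weights of the best-validation epoch.

    Epoch selection maximizes plain validation accuracy (fraction of
    correct binarized predictions); the earliest epoch wins ties.  Returns
    (model with selected weights, selected epoch index, per-epoch history).
    """
    config = config or model.config
    Xp_tr, Xf_tr, y_tr = train
    Xp_va, Xf_va, y_va = val
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValueError("train and val must be non-empty")
    if len(y_va) == 1:
        logger.warning("validation set has a single record")
    rng = rng_for(config.seed, "train")
    n = len(y_tr)
    best_acc, best_epoch, best_weights = -np.inf, -1, None
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            prob, cache = model.forward(Xp_tr[idx], Xf_tr[idx], train=True, rng=rng)
            eps = 1e-12
            losses.append(
                -np.mean(
                    y_tr[idx] * np.log(prob + eps)
                    + (1 - y_tr[idx]) * np.log(1 - prob + eps)
                )
            )
            grads = model._backward(prob, y_tr[idx], cache)
            model._adam_step(grads)
        val_scores = _predict_in_batches(model, Xp_va, Xf_va, config.batch_size)
        val_acc = float(np.mean((val_scores >= 0.5) == y_va))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": val_acc}
        )
        if val_acc > best_acc:  # strict: earliest epoch wins ties
            best_acc, best_epoch = val_acc, epoch
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return model, best_epoch, history


def _predict_in_batches(
    model: PCMNetwork, Xp: np.ndarray, Xf: np.ndarray, batch_size: int
) -> np.ndarray:
    out = [
        model.predict_scores(Xp[i : i + batch_size], Xf[i : i + batch_size])
        for i in range(0, len(Xf), batch_size)
    ]
    return np.concatenate(out) if out else np.empty(0)


def predict(
    model,
    pairs: list[tuple[str, str]],
    fingerprints: dict[str, np.ndarray],
    sequences: dict[str, str],
    batch_size: int = 128,
) -> np.ndarray:
    """Scores in [0, 1] for (compound_id, protein_id) pairs, order preserved.

    Unknown identifiers raise KeyError.  Works for both the CNN+FFN network
    and the logistic surrogate.
    """
    if not pairs:
        return np.empty(0)
    for cid, pid in pairs:
        if cid not in fingerprints:
            raise KeyError(f"unknown compound_id {cid!r}")
        if pid not in sequences:
            raise KeyError(f"unknown protein_id {pid!r}")
    if isinstance(model, LogisticSurrogate):
        return model.predict_pairs(pairs, fingerprints, sequences)
    cache: dict[str, np.ndarray] = {}
    records = [
        BioactivityRecord(compound_id=c, protein_id=p, label=0) for c, p in pairs
    ]
    Xp, Xf, _ = encode_batch(records, fingerprints, sequences, protein_cache=cache)
    return _predict_in_batches(model, Xp, Xf, batch_size)


class LogisticSurrogate:
    """Fast stand-in classifier for desk-scale benchmark runs.

    Logistic regression on the fingerprint bits concatenated with cheap
    protein features (normalized length and amino-acid composition).  The
    balance-accounting conclusions of the benchmark do not depend on model
    capacity, so the surrogate lets the full loop run in seconds.
    """

    def __init__(self, seed: int = 0, C: float = 1.0):
        from sklearn.linear_model import LogisticRegression

        self.clf = LogisticRegression(max_iter=500, C=C, random_state=seed % (2**31))
        self._protein_features: dict[str, np.ndarray] = {}

    def _featurize_protein(self, pid: str, sequences: dict[str, str]) -> np.ndarray:
        if pid not in self._protein_features:
            seq = sequences[pid]
            comp = np.zeros(26)
            for ch in seq:
                comp[(ord(ch) - ord("A")) % 26] += 1
            comp = comp / max(len(seq), 1)
            self._protein_features[pid] = np.concatenate(
                [[len(seq) / MAX_SEQUENCE_LENGTH], comp]
            )
        return self._protein_features[pid]

    def _design(self, records, fingerprints, sequences) -> np.ndarray:
        return np.stack(
            [
                np.concatenate(
                    [
                        fingerprints[r.compound_id],
                        self._featurize_protein(r.protein_id, sequences),
                    ]
                )
                for r in records
            ]
        )

    def fit(self, records, fingerprints, sequences) -> "LogisticSurrogate":
        X = self._design(records, fingerprints, sequences)
        y = np.array([r.label for r in records])
        if len(np.unique(y)) < 2:  # degenerate training set: constant scores
            self._constant = float(y.mean())
            return self
        self._constant = None
        self.clf.fit(X, y)
        return self

    def predict_pairs(self, pairs, fingerprints, sequences) -> np.ndarray:
        records = [
            BioactivityRecord(compound_id=c, protein_id=p, label=0) for c, p in pairs
        ]
        if getattr(self, "_constant", None) is not None:
            return np.full(len(records), self._constant)
        X = self._design(records, fingerprints, sequences)
        return self.clf.predict_proba(X)[:, 1]
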