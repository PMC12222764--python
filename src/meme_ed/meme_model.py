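"""The multi-embedding fusion head and its ablation variants.

The full model ("meme") treats an encounter's six concept embeddings as a
length-6 sequence, applies scaled dot-product self-attention with learned
query/key/value projections, flattens, and passes the result through a
fully connected ReLU layer and a linear classifier.  The attention acts as
a feature selector over EHR concepts: its rows are simplex-valued weights
saying how much each concept attends to the others.  The "msem" ablation
replaces the six embeddings with a single embedding of the whole
concatenated narrative and a linear classifier (no attention); a
"single:<concept>" ablation feeds one stream through the same head with
sequence length 1.

Encoders are frozen: embeddings enter as constants and only head
parameters are trained, by minibatch Adam on summed sigmoid binary
cross-entropy (one logit for disposition, three independent logits for
decompensation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from meme_ed import nn
from meme_ed.concepts import CONCEPT_ORDER, N_CONCEPTS, ConceptKind
from meme_ed.encoders import ConceptEmbedding

VARIANTS = ("meme", "msem") + tuple(f"single:{k.value}" for k in CONCEPT_ORDER)


@dataclass(frozen=True)
class PatientRepresentation:
    """Ordered sequence of the six concept embeddings for one encounter."""

    embeddings: tuple[ConceptEmbedding, ...]

    def __post_init__(self) -> None:
        kinds = tuple(e.concept for e in self.embeddings)
        if kinds != CONCEPT_ORDER:
            raise ValueError(
                f"embeddings must follow canonical concept order, got {kinds}"
            )
        dims = {e.vector.shape[-1] for e in self.embeddings}
        if len(dims) != 1:
            raise ValueError("concept embeddings have mixed dimensions")

    @property
    def matrix(self) -> np.ndarray:
        """(6, dim) stack in canonical order."""
        return np.stack([e.vector for e in self.embeddings])

    @property
    def concat_vector(self) -> np.ndarray:
        """In-order concatenation, length 6*dim."""
        return self.matrix.reshape(-1)


@dataclass(frozen=True)
class MemeHyperparams:
    """Training knobs of the head (the backbone stays frozen)."""

    n_heads: int = 1
    fc_width: int = 256
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 128
    weight_decay: float = 1e-5
    patience: int = 3
    seed: int = 0
    task_mode: str = "binary"  # or "multilabel"

    def __post_init__(self) -> None:
        if self.task_mode not in ("binary", "multilabel"):
            raise ValueError(f"unknown task_mode {self.task_mode!r}")
        for name in ("n_heads", "fc_width", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_out(self) -> int:
        return 1 if self.task_mode == "binary" else 3


@dataclass
class MemeModelState:
    """Trained head parameters plus training metadata.

    Encoder parameters are deliberately not part of the state; only the
    attention/FC/classifier arrays are.  Round-trips through disk exactly
    (float32 arrays in an .npz, metadata in a JSON sidecar).
    """

    kind: str
    dim: int
    hyperparams: MemeHyperparams
    arrays: dict[str, np.ndarray]
    train_log: list[dict] = field(default_factory=list)
    encoder_fingerprint: str = ""

    def build_model(self) -> nn.Sequential:
        model = build_variant(self.kind, self.dim, self.hyperparams)
        model.load_state_arrays(self.arrays)
        return model

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.arrays)
        meta = {
            "kind": self.kind,
            "dim": self.dim,
            "hyperparams": asdict(self.hyperparams),
            "train_log": self.train_log,
            "encoder_fingerprint": self.encoder_fingerprint,
            "concept_order": [k.value for k in CONCEPT_ORDER],
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "MemeModelState":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as npz:
            arrays = {k: npz[k].copy() for k in npz.files}
        return cls(
            kind=meta["kind"],
            dim=meta["dim"],
            hyperparams=MemeHyperparams(**meta["hyperparams"]),
            arrays=arrays,
            train_log=meta["train_log"],
            encoder_fingerprint=meta["encoder_fingerprint"],
        )


# ---------------------------------------------------------------------------
# assembly


def build_variant(
    kind: str, dim: int, hp: MemeHyperparams, rng: np.random.Generator | None = None
) -> nn.Sequential:
    """Assemble a head variant.

    ``meme``: attention over 6 concept positions -> flatten -> FC+ReLU ->
    classifier.  ``msem``: linear classifier on one whole-narrative
    embedding.  ``single:<concept>``: the meme head with sequence length 1.
    """
    rng = rng or np.random.default_rng(hp.seed)
    if kind == "meme":
        seq_len = N_CONCEPTS
    elif kind == "msem":
        return nn.Sequential([nn.Dense(dim, hp.n_out, rng)])
    elif kind.startswith("single:"):
        ConceptKind(kind.split(":", 1)[1])  # raises on unknown concept
        seq_len = 1
    else:
        raise ValueError(f"unknown variant kind {kind!r}")
    return nn.Sequential([
        nn.SelfAttention(dim, hp.n_heads, rng),
        nn.Flatten(),
        nn.Dense(seq_len * dim, hp.fc_width, rng),
        nn.ReLU(),
        nn.Dense(hp.fc_width, hp.n_out, rng),
    ])


def single_concept_input(
    X: np.ndarray, concept: ConceptKind | str
) -> np.ndarray:
    """Slice one stream out of a (n, 6, dim) embedding tensor -> (n, 1, dim)."""
    idx = CONCEPT_ORDER.index(ConceptKind(concept))
    return X[:, idx : idx + 1, :]


# ---------------------------------------------------------------------------
# forward paths


def _as_batch(rep, kind: str) -> np.ndarray:
    if isinstance(rep, PatientRepresentation):
        x = rep.matrix[None, ...]
    else:
        x = np.asarray(rep, dtype=nn.DTYPE)
        if kind == "msem":
            if x.ndim == 1:
                x = x[None, :]
        elif x.ndim == 2:
            x = x[None, ...]
    return x.astype(nn.DTYPE, copy=False)


def fuse_self_attention(rep, state: MemeModelState) -> np.ndarray:
    """Apply the trained attention layer; return the flattened fused vector."""
    if state.kind == "msem":
        raise ValueError("msem variant has no attention layer")
    x = _as_batch(rep, state.kind)
    model = state.build_model()
    attn = model.layers[0]
    if x.shape[-1] != state.dim:
        raise ValueError(f"input dim {x.shape[-1]} != model dim {state.dim}")
    fused = attn.forward(x, train=False)
    out = fused.reshape(fused.shape[0], -1)
    return out[0] if (isinstance(rep, PatientRepresentation) or np.asarray(rep).ndim == 2) else out


def attention_weights(rep, state: MemeModelState) -> np.ndarray:
    """(heads, T, T) attention weight rows for one representation."""
    if state.kind == "msem":
        raise ValueError("msem variant has no attention layer")
    x = _as_batch(rep, state.kind)
    model = state.build_model()
    model.layers[0].forward(x, train=False)
    return model.layers[0].last_attention[0]


def forward(rep, state: MemeModelState) -> np.ndarray:
    """Logits for one representation or a batch (inference mode)."""
    x = _as_batch(rep, state.kind)
    model = state.build_model()
    logits = model.forward(x, train=False)
    single = isinstance(rep, PatientRepresentation) or (
        np.asarray(rep).ndim == (1 if state.kind == "msem" else 2)
    )
    return logits[0] if single else logits


def predict_proba(state: MemeModelState, X: np.ndarray) -> np.ndarray:
    """(n, n_out) sigmoid probabilities in inference mode."""
    model = state.build_model()
    logits = model.forward(np.asarray(X, dtype=nn.DTYPE), train=False)
    return 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))


# ---------------------------------------------------------------------------
# losses (per-logit sigmoid cross-entropy, summed)


def multilabel_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Sum over observations and labels of per-logit sigmoid BCE.

    Logits are clamped to ±30 before the stable log-sum-exp form, which
    bounds each term without affecting any realistic optimisation state.
    """
    z = np.atleast_2d(np.asarray(logits, dtype=float))
    y = np.atleast_2d(np.asarray(labels, dtype=float))
    if z.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {z.shape} vs labels {y.shape}")
    return nn.bce_with_logits_sum(z, y)


def binary_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Single-logit sigmoid cross-entropy (the m=1 multilabel case)."""
    z = np.asarray(logits, dtype=float).reshape(-1, 1)
    y = np.asarray(labels, dtype=float).reshape(-1, 1)
    if z.shape != y.shape:
        raise ValueError("logits and labels must have equal length")
    return nn.bce_with_logits_sum(z, y)


# ---------------------------------------------------------------------------
# training


def train_head(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    hp: MemeHyperparams = MemeHyperparams(),
    kind: str = "meme",
    encoder_fingerprint: str = "",
) -> MemeModelState:
    """Minibatch Adam on the task loss; returns the best-validation state.

    Embeddings are precomputed constants (the encoder is frozen), so the
    only trained parameters are the head's.  Fully reproducible given
    fixed hyperparameters, inputs and seed.
    """
    X_train = np.asarray(X_train, dtype=nn.DTYPE)
    X_val = np.asarray(X_val, dtype=nn.DTYPE)
    if len(X_val) == 0:
        raise ValueError("validation set must be non-empty")
    y_train = np.asarray(y_train, dtype=np.float64).reshape(len(X_train), -1)
    y_val = np.asarray(y_val, dtype=np.float64).reshape(len(X_val), -1)
    if y_train.shape[1] != hp.n_out:
        raise ValueError(
            f"labels have {y_train.shape[1]} columns but task_mode "
            f"{hp.task_mode!r} expects {hp.n_out}"
        )

    rng = np.random.default_rng(hp.seed)
    dim = X_train.shape[-1]
    model = build_variant(kind, dim, hp, rng)
    opt = nn.Adam(model, lr=hp.learning_rate, weight_decay=hp.weight_decay)

    n = len(X_train)
    best_val = np.inf
    best_arrays: dict[str, np.ndarray] | None = None
    log: list[dict] = []
    stall = 0

    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            logits = model.forward(xb, train=True)
            batch_loss = nn.bce_with_logits_sum(logits, yb)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {start}: "
                    f"{batch_loss!r}"
                )
            epoch_loss += batch_loss
            grad = nn.bce_with_logits_grad(logits, yb) / len(idx)
            model.backward(grad)
            opt.step()
        train_loss = epoch_loss / n
        val_logits = model.forward(X_val, train=False)
        val_loss = nn.bce_with_logits_sum(val_logits, y_val) / len(X_val)
        log.append({"epoch": epoch, "train_loss": float(train_loss),
                    "val_loss": float(val_loss)})
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_arrays = {k: v.copy() for k, v in model.state_arrays().items()}
            stall = 0
        else:
            stall += 1
            if stall >= hp.patience:
                break

    assert best_arrays is not None
    return MemeModelState(
        kind=kind,
        dim=dim,
        hyperparams=hp,
        arrays=best_arrays,
        train_log=log,
        encoder_fingerprint=encoder_fingerprint,
    )


def fine_tune_head(
    state: MemeModelState,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 10,
    learning_rate: float = 3e-4,
    batch_size: int = 32,
    seed: int = 0,
) -> MemeModelState:
    """Continue training a head on a (possibly tiny) adaptation sample.

    Used by the few-shot protocol: parameters start from the source
    institution's state, the encoder stays frozen, and a fixed number of
    low-rate Adam epochs is run (no validation-based early stop — the
    adaptation sample may be just a handful of encounters).
    """
    X = np.asarray(X, dtype=nn.DTYPE)
    y = np.asarray(y, dtype=np.float64).reshape(len(X), -1)
    rng = np.random.default_rng(seed)
    model = state.build_model()
    opt = nn.Adam(model, lr=learning_rate,
                  weight_decay=state.hyperparams.weight_decay)
    n = len(X)
    log = list(state.train_log)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = model.forward(X[idx], train=True)
            epoch_loss += nn.bce_with_logits_sum(logits, y[idx])
            grad = nn.bce_with_logits_grad(logits, y[idx]) / len(idx)
            model.backward(grad)
            opt.step()
        log.append({"fine_tune_epoch": epoch, "train_loss": float(epoch_loss / n)})
    return MemeModelState(
        kind=state.kind,
        dim=state.dim,
        hyperparams=state.hyperparams,
        arrays=model.state_arrays(),
        train_log=log,
        encoder_fingerprint=state.encoder_fingerprint,
    )
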