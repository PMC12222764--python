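"""Frozen text encoders: pseudo-note -> fixed-dimension vector.

Two backends share one contract.  ``hashed-projection`` is a fully offline,
deterministic encoder: token-hashed bag-of-words mapped through a seeded
fixed Gaussian projection and L2-normalized.  ``pretrained-transformer``
wraps a HuggingFace encoder when the ``transformers`` package and weights
are available locally; its parameters are never updated.  Either way the
encoder is frozen — downstream training sees embeddings as constants.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from meme_ed.concepts import CONCEPT_ORDER, ConceptKind
from meme_ed.pseudonotes import ConceptNote

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:[.-][a-z0-9]+)*")
_N_BUCKETS = 4096
_EMPTY_TOKEN = "<empty>"


class EncoderBackendUnavailable(RuntimeError):
    """The requested encoder backend cannot run in this environment."""


@dataclass(frozen=True)
class EncoderSpec:
    """Configuration of a frozen note encoder.

    ``backend`` is ``"hashed-projection"`` or ``"pretrained-transformer"``;
    ``model_name`` applies to the transformer backend only, ``seed`` to the
    hashed backend only.  ``pooling`` is ``"first-token"`` (CLS-style) or
    ``"mean"`` for transformer backends; the hashed backend pools by
    construction.
    """

    backend: str = "hashed-projection"
    dim: int = 768
    max_tokens: int = 512
    pooling: str = "first-token"
    seed: int = 0
    model_name: str = ""

    def __post_init__(self) -> None:
        if self.backend not in ("hashed-projection", "pretrained-transformer"):
            raise ValueError(f"unknown encoder backend {self.backend!r}")
        if self.dim < 8:
            raise ValueError("dim must be >= 8")
        if self.pooling not in ("first-token", "mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "backend": self.backend, "dim": self.dim,
                "max_tokens": self.max_tokens, "pooling": self.pooling,
                "seed": self.seed, "model_name": self.model_name,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ConceptEmbedding:
    key: object
    concept: ConceptKind | str
    vector: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding has non-finite entries")


# ---------------------------------------------------------------------------
# hashed-projection backend


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def _token_bucket(token: str) -> int:
    digest = hashlib.blake2b(token.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % _N_BUCKETS


_projection_cache: dict[tuple[int, int], np.ndarray] = {}


def _projection(dim: int, seed: int) -> np.ndarray:
    key = (dim, seed)
    if key not in _projection_cache:
        rng = np.random.default_rng(seed)
        _projection_cache[key] = rng.standard_normal(
            (_N_BUCKETS, dim)
        ).astype(np.float32) / np.sqrt(dim)
    return _projection_cache[key]


def _bow_counts(texts: Sequence[str], max_tokens: int) -> sp.csr_matrix:
    indptr, indices, data = [0], [], []
    for text in texts:
        tokens = tokenize(text)[:max_tokens] or [_EMPTY_TOKEN]
        counts: dict[int, float] = {}
        for tok in tokens:
            b = _token_bucket(tok)
            counts[b] = counts.get(b, 0.0) + 1.0
        indices.extend(counts)
        data.extend(counts.values())
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data, dtype=np.float32), indices, indptr),
        shape=(len(texts), _N_BUCKETS),
    )


def hashed_projection_encode(
    text: str, dim: int = 768, seed: int = 0, max_tokens: int = 512
) -> np.ndarray:
    """Bag-of-words token hashing + fixed seeded projection, L2-normalized.

    Pure function of (text, dim, seed): word order does not matter, and a
    text with no tokens maps to the constant vector of the ``<empty>``
    marker token, so every output has unit norm.
    """
    return hashed_projection_encode_many([text], dim, seed, max_tokens)[0]


def hashed_projection_encode_many(
    texts: Sequence[str], dim: int = 768, seed: int = 0, max_tokens: int = 512
) -> np.ndarray:
    bow = _bow_counts(texts, max_tokens)
    vecs = np.asarray(bow @ _projection(dim, seed), dtype=np.float32)
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vecs / norms


# ---------------------------------------------------------------------------
# transformer backend (requires local weights; never trained)


def _transformer_encode_many(texts: Sequence[str], spec: EncoderSpec) -> np.ndarray:
    try:
        import torch  # noqa: F401
        from transformers import AutoModel, AutoTokenizer
    except ImportError as exc:
        raise EncoderBackendUnavailable(
            "the pretrained-transformer backend needs the 'torch' and "
            "'transformers' packages with locally downloaded weights; use "
            "backend='hashed-projection' for a fully offline encoder"
        ) from exc
    import torch

    tok = AutoTokenizer.from_pretrained(spec.model_name)
    model = AutoModel.from_pretrained(spec.model_name)
    model.eval()
    out = []
    with torch.no_grad():
        for text in texts:
            enc = tok(text, truncation=True, max_length=spec.max_tokens,
                      return_tensors="pt")
            hidden = model(**enc).last_hidden_state[0]
            if spec.pooling == "first-token":
                vec = hidden[0]
            else:
                vec = hidden.mean(dim=0)
            out.append(vec.numpy().astype(np.float32))
    return np.stack(out)


# ---------------------------------------------------------------------------
# public encoding API


def encode_note(note: ConceptNote, spec: EncoderSpec = EncoderSpec()) -> ConceptEmbedding:
    """Encode one pseudo-note with the frozen encoder.

    Text is tokenized and truncated to ``spec.max_tokens`` before encoding;
    fallback notes are encoded like any other text.  Deterministic for a
    fixed spec.
    """
    if not note.text:
        raise ValueError("note text must be non-empty")
    return ConceptEmbedding(note.key, note.concept, encode_texts([note.text], spec)[0])


def encode_texts(texts: Sequence[str], spec: EncoderSpec = EncoderSpec()) -> np.ndarray:
    if spec.backend == "hashed-projection":
        return hashed_projection_encode_many(
            texts, dim=spec.dim, seed=spec.seed, max_tokens=spec.max_tokens
        )
    return _transformer_encode_many(texts, spec)


# ---------------------------------------------------------------------------
# cohort-level embedding store


class EmbeddingStore:
    """Per-(encounter, concept) embedding matrix with a spec fingerprint.

    ``matrix`` has one row per note; ``index`` maps
    (encounter_id, concept) -> row.  Persisted as a ``.npy`` matrix plus a
    JSON sidecar carrying keys, concept order, and the encoder fingerprint.
    """

    def __init__(self, matrix: np.ndarray, records: list[tuple[str, str]],
                 fingerprint: str):
        self.matrix = matrix
        self.records = records
        self.fingerprint = fingerprint
        self.index = {rec: i for i, rec in enumerate(records)}

    def __len__(self) -> int:
        return len(self.records)

    def vector(self, encounter_id: str, concept: ConceptKind | str) -> np.ndarray:
        name = concept.value if isinstance(concept, ConceptKind) else str(concept)
        return self.matrix[self.index[(encounter_id, name)]]

    def encounter_matrix(self, encounter_id: str) -> np.ndarray:
        """(6, dim) matrix in canonical concept order."""
        rows = [self.index[(encounter_id, k.value)] for k in CONCEPT_ORDER]
        return self.matrix[rows]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.matrix)
        sidecar = {
            "fingerprint": self.fingerprint,
            "records": self.records,
            "concept_order": [k.value for k in CONCEPT_ORDER],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingStore":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        matrix = np.load(path.with_suffix(".npy"))
        return cls(matrix, [tuple(r) for r in sidecar["records"]],
                   sidecar["fingerprint"])


class StaleCacheError(RuntimeError):
    """Cached embeddings were produced under a different encoder spec."""


def embed_cohort(
    notes: Iterable[ConceptNote],
    spec: EncoderSpec = EncoderSpec(),
    cache_path: str | Path | None = None,
) -> EmbeddingStore:
    """Embed every note; optionally persist/reuse a fingerprinted cache.

    A cache whose fingerprint matches the spec is reused bit-exactly; a
    mismatched fingerprint raises :class:`StaleCacheError` rather than
    silently mixing encoders.
    """
    notes = list(notes)
    fingerprint = spec.fingerprint()
    if cache_path is not None:
        cache_path = Path(cache_path)
        if cache_path.with_suffix(".json").exists():
            store = EmbeddingStore.load(cache_path)
            if store.fingerprint != fingerprint:
                raise StaleCacheError(
                    f"cache at {cache_path} has fingerprint "
                    f"{store.fingerprint}, expected {fingerprint}"
                )
            return store
    texts = [n.text for n in notes]
    matrix = encode_texts(texts, spec)
    records = [
        (
            n.key.encounter_id,
            n.concept.value if isinstance(n.concept, ConceptKind) else str(n.concept),
        )
        for n in notes
    ]
    store = EmbeddingStore(matrix, records, fingerprint)
    if cache_path is not None:
        store.save(cache_path)
    return store
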