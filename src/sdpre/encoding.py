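"""Encoder contract: token embeddings plus final-layer attention.

Downstream representation building needs three things from an encoder: a
sentence vector ``h_cls``, a word-level embedding matrix ``H`` and the
final-layer self-attention tensor ``A`` with rows normalized per query.
Two providers satisfy that contract:

* :class:`StubEncoder` — a deterministic hash-based encoder for testing and
  synthetic experiments.  Each token's vector is Gaussian noise keyed by
  its surface form; designated *trigger* surfaces additionally receive a
  class-signal offset ``delta * e_r`` along a fixed per-class direction.
  This makes relation signal linearly separable by construction while
  exercising every code path a real transformer would.
* :class:`PretrainedEncoder` — an optional adapter over any Hugging Face
  transformer that exposes attentions.  It is never required by tests and
  imports ``transformers`` lazily.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EncoderConfig",
    "EncoderOutput",
    "EncodingError",
    "StubEncoder",
    "PretrainedEncoder",
    "align_subwords",
]


class EncodingError(ValueError):
    """Input violates the encoder contract (e.g. sentence too long)."""


@dataclass(frozen=True)
class EncoderOutput:
    """Sentence vector, per-word embeddings and word-level attention.

    ``A`` has shape ``(n_heads, n_words, n_words)``; every row ``A[h, q]``
    is a probability distribution over key positions.
    """

    h_cls: np.ndarray
    H: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        if self.H.ndim != 2 or self.A.ndim != 3:
            raise EncodingError("H must be 2-D and A 3-D")
        n = self.H.shape[0]
        if self.A.shape[1:] != (n, n):
            raise EncodingError(f"attention shape {self.A.shape} inconsistent with {n} words")
        rowsums = self.A.sum(axis=-1)
        if not np.allclose(rowsums, 1.0, atol=1e-6):
            raise EncodingError("attention rows must sum to 1 within 1e-6")

    @property
    def L(self) -> int:
        return self.H.shape[1]

    @property
    def n_words(self) -> int:
        return self.H.shape[0]

    @property
    def n_heads(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class EncoderConfig:
    """Stub-encoder settings.

    ``trigger_classes`` maps trigger surfaces to class indices; such tokens
    receive an additive offset of magnitude ``delta`` along a fixed,
    seed-derived unit direction for their class.  All tokens receive
    surface-keyed Gaussian noise of scale ``sigma``.  Small default width
    and head count keep desk-scale runs fast while leaving the per-head
    dimension nontrivial.
    """

    L: int = 16
    n_heads: int = 2
    max_len: int = 64
    seed: int = 0
    sigma: float = 1.0
    delta: float = 0.0
    trigger_classes: dict[str, int] = field(default_factory=dict)


def _hash_seed(*parts: object) -> int:
    digest = hashlib.blake2b("\x1f".join(map(str, parts)).encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big")


class StubEncoder:
    """Deterministic, training-free encoder: a pure function of (tokens, config)."""

    def __init__(self, config: EncoderConfig | None = None):
        self.config = config or EncoderConfig()

    def class_direction(self, class_index: int) -> np.ndarray:
        """Fixed unit vector for one relation class, derived from the seed."""
        rng = np.random.default_rng(_hash_seed(self.config.seed, "class", class_index))
        v = rng.standard_normal(self.config.L)
        return v / np.linalg.norm(v)

    def _token_vector(self, surface: str, context_key: str) -> np.ndarray:
        # Noise is keyed by (surface, bag of sentence surfaces): the same word
        # gets the same vector within a sentence but varies across sentences,
        # like a contextual encoder.  Keying on the *sorted* bag keeps the
        # vector order-independent, so permuting tokens permutes H rows.
        # sigma and delta are both vector magnitudes: noise is scaled by 1/sqrt(L)
        # so E||noise|| ≈ sigma, directly comparable to the offset norm delta.
        cfg = self.config
        rng = np.random.default_rng(_hash_seed(cfg.seed, "tok", surface, context_key))
        vec = cfg.sigma * rng.standard_normal(cfg.L) / np.sqrt(cfg.L)
        cls = cfg.trigger_classes.get(surface)
        if cls is not None:
            vec = vec + cfg.delta * self.class_direction(cls)
        return vec

    def encode(self, tokens: list[str]) -> EncoderOutput:
        cfg = self.config
        if len(tokens) > cfg.max_len:
            raise EncodingError(f"sentence of {len(tokens)} tokens exceeds max_len={cfg.max_len}")
        if not tokens:
            raise EncodingError("cannot encode an empty sentence")
        context_key = "\x1e".join(sorted(tokens))
        H = np.stack([self._token_vector(s, context_key) for s in tokens])
        h_cls = H.mean(axis=0)
        # Per-head attention from scaled bilinear scores; softmax rows.
        n = len(tokens)
        A = np.empty((cfg.n_heads, n, n))
        for h in range(cfg.n_heads):
            rng = np.random.default_rng(_hash_seed(cfg.seed, "head", h))
            P = rng.standard_normal((cfg.L, cfg.L)) / np.sqrt(cfg.L)
            scores = (H @ P @ H.T) / np.sqrt(cfg.L)
            scores -= scores.max(axis=1, keepdims=True)
            e = np.exp(scores)
            A[h] = e / e.sum(axis=1, keepdims=True)
        return EncoderOutput(h_cls=h_cls, H=H, A=A)

    __call__ = encode


def align_subwords(
    subword_embeddings: np.ndarray,
    subword_attention: np.ndarray,
    alignment: list[list[int]],
    h_cls: np.ndarray | None = None,
) -> EncoderOutput:
    """Collapse subword-level encoder output to word level.

    A word's embedding is its *first* subword's embedding; its attention
    row is the first subword's query row with key columns summed over each
    word's subwords, then renormalized.  ``alignment`` lists, per word, the
    subword indices it spans (each word needs at least one).
    """
    for w, subs in enumerate(alignment):
        if not subs:
            raise EncodingError(f"word {w} maps to no subwords")
    firsts = [subs[0] for subs in alignment]
    H = subword_embeddings[firsts]
    n_heads = subword_attention.shape[0]
    n_words = len(alignment)
    A = np.empty((n_heads, n_words, n_words))
    for h in range(n_heads):
        rows = subword_attention[h][firsts]  # (n_words, n_subwords)
        pooled = np.stack([rows[:, subs].sum(axis=1) for subs in alignment], axis=1)
        A[h] = pooled / pooled.sum(axis=1, keepdims=True)
    if h_cls is None:
        h_cls = H.mean(axis=0)
    return EncoderOutput(h_cls=h_cls, H=H, A=A)


class PretrainedEncoder:
    """Adapter over a Hugging Face transformer exposing final-layer attentions.

    Requires the optional ``transformers`` and ``torch`` packages; weights
    are downloaded only if the user opts in by constructing this class.
    Output is aligned to word level via :func:`align_subwords`.
    """

    def __init__(self, model_name: str, max_len: int = 200):
        try:
            from transformers import AutoModel, AutoTokenizer  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "PretrainedEncoder requires the optional 'transformers' and 'torch' "
                "packages; the StubEncoder needs neither"
            ) from exc
        self.tokenizer = AutoTokenizer.from_pretrained(model_name)
        self.model = AutoModel.from_pretrained(model_name, output_attentions=True)
        self.model.eval()
        self.max_len = max_len

    def encode(self, tokens: list[str]) -> EncoderOutput:  # pragma: no cover - optional
        import torch  # type: ignore

        enc = self.tokenizer(tokens, is_split_into_words=True, return_tensors="pt")
        if enc["input_ids"].shape[1] > self.max_len:
            raise EncodingError(f"sentence exceeds max_len={self.max_len} subwords")
        with torch.no_grad():
            out = self.model(**enc)
        emb = out.last_hidden_state[0].numpy()
        att = out.attentions[-1][0].numpy()
        word_ids = enc.word_ids(0)
        alignment: list[list[int]] = [[] for _ in range(len(tokens))]
        for sub, w in enumerate(word_ids):
            if w is not None:
                alignment[w].append(sub)
        return align_subwords(emb, att, alignment, h_cls=emb[0])

    __call__ = encode
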