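"""Pluggable text-encoder contract with a desk-scale default backend.

The default backend hashes word n-grams into a fixed-width signed feature
space (the "hashing trick") and feeds a multi-head linear model, one logit
per outcome. The contract — featurize text, emit one finite log-odds value
per outcome per document — is what the distillation pipeline requires; a
transformer backbone would plug in behind the same ``external`` hook.

Hashing uses CRC32 with an explicit seed so featurization is deterministic
across processes. A second salted hash supplies the feature sign, the
standard variance-reduction trick for hashed features.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

from .documents import (
    ConfigurationError,
    Document,
    LabelSchema,
    SchemaMismatchError,
    prepare_tokens,
    tokenize,
)


@dataclass(frozen=True)
class EncoderConfig:
    """Hashed n-gram featurizer settings.

    ``n_features`` must be a power of two (keeps hashing uniform and the
    model file size predictable); ``ngram_range`` is inclusive over word
    n-gram orders.
    """

    n_features: int = 8192
    ngram_range: tuple[int, int] = (1, 2)
    hash_seed: int = 0
    backend: str = "hashed_linear"

    def __post_init__(self) -> None:
        n = self.n_features
        if n < 2 or (n & (n - 1)) != 0:
            raise ConfigurationError("n_features must be a power of two >= 2")
        lo, hi = self.ngram_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("ngram_range must satisfy 1 <= min_n <= max_n")
        if self.backend not in ("hashed_linear", "external"):
            raise ConfigurationError(f"unknown backend {self.backend!r}")


def hash_index(term: str, config: EncoderConfig) -> int:
    """Bucket index of an n-gram term (deterministic, seed-keyed CRC32)."""
    h = zlib.crc32(f"{config.hash_seed}|{term}".encode("utf-8"))
    return h % config.n_features


def hash_sign(term: str, config: EncoderConfig) -> int:
    """Signed-hashing sign (+1/-1) of an n-gram term."""
    h = zlib.crc32(f"sign|{config.hash_seed}|{term}".encode("utf-8"))
    return 1 if h & 1 else -1


def _ngrams(tokens: Sequence[str], lo: int, hi: int):
    for n in range(lo, hi + 1):
        for i in range(len(tokens) - n + 1):
            yield " ".join(tokens[i : i + n])


def featurize_tokens(tokens: Sequence[str], config: EncoderConfig) -> dict[int, float]:
    """Signed hashed n-gram counts of a token sequence, as {index: value}."""
    lo, hi = config.ngram_range
    counts: dict[int, float] = {}
    for term in _ngrams(tokens, lo, hi):
        idx = hash_index(term, config)
        counts[idx] = counts.get(idx, 0.0) + hash_sign(term, config)
    return counts


def featurize(text: str, config: EncoderConfig) -> sp.csr_matrix:
    """Featurize one raw text (no truncation policy applied)."""
    return featurize_corpus([tokenize(text)], config)


def featurize_corpus(
    token_lists: Sequence[Sequence[str]], config: EncoderConfig
) -> sp.csr_matrix:
    """Featurize pre-tokenized documents into an (n_docs, n_features) CSR."""
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for tokens in token_lists:
        counts = featurize_tokens(tokens, config)
        for idx in sorted(counts):
            v = counts[idx]
            if v != 0.0:
                indices.append(idx)
                data.append(v)
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int32), np.asarray(indptr)),
        shape=(len(token_lists), config.n_features),
    )


def featurize_documents(docs: Sequence[Document], config: EncoderConfig) -> sp.csr_matrix:
    """Featurize documents after per-doc-type truncation."""
    return featurize_corpus([prepare_tokens(d) for d in docs], config)


# ---------------------------------------------------------------------------
# Multi-head linear model
# ---------------------------------------------------------------------------


@dataclass
class MultiHeadModel:
    """A linear model with one binary classification/regression head per
    outcome, over hashed n-gram features.

    ``weights`` has shape (n_features, n_heads); ``bias`` shape (n_heads,).
    ``meta`` carries training metadata (loss trace, epochs, seed, provenance).
    Prediction is deterministic given the parameters.
    """

    config: EncoderConfig
    schema: LabelSchema
    weights: np.ndarray
    bias: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.shape != (self.config.n_features, len(self.schema)):
            raise SchemaMismatchError(
                f"weights shape {self.weights.shape} does not match "
                f"({self.config.n_features}, {len(self.schema)})"
            )
        if self.bias.shape != (len(self.schema),):
            raise SchemaMismatchError("bias shape does not match schema size")

    @classmethod
    def zeros(
        cls, config: EncoderConfig, schema: LabelSchema, meta: dict | None = None
    ) -> "MultiHeadModel":
        return cls(
            config=config,
            schema=schema,
            weights=np.zeros((config.n_features, len(schema))),
            bias=np.zeros(len(schema)),
            meta=meta or {},
        )

    # -- inference ---------------------------------------------------------

    def logits_from_features(self, X: sp.spmatrix) -> np.ndarray:
        return np.asarray(X @ self.weights) + self.bias

    def predict_logits(
        self, docs: Sequence[Document], outcomes: Sequence[str] | None = None
    ):
        """Predicted log odds per outcome per document, as a doc_id-indexed
        DataFrame in schema order."""
        import pandas as pd

        if outcomes is not None:
            missing = [o for o in outcomes if o not in self.schema.outcomes]
            if missing:
                raise SchemaMismatchError(f"model has no heads for {missing}")
        X = featurize_documents(docs, self.config)
        Z = self.logits_from_features(X)
        frame = pd.DataFrame(
            Z, index=pd.Index([d.doc_id for d in docs], name="doc_id"),
            columns=list(self.schema.outcomes),
        )
        return frame if outcomes is None else frame[list(outcomes)]

    def predict_proba(self, docs: Sequence[Document]):
        return self.predict_logits(docs).apply(expit)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize to a single portable file (schema, config, parameters).

        This file is the shareable artifact: it contains no document text and
        no per-document features, only the learned parameters.
        """
        header = json.dumps(
            {
                "config": {**asdict(self.config), "ngram_range": list(self.config.ngram_range)},
                "schema": {"name": self.schema.name, "outcomes": list(self.schema.outcomes)},
                "meta": self.meta,
            }
        )
        with open(path, "wb") as fh:
            np.savez(fh, header=np.array(header), weights=self.weights, bias=self.bias)

    @classmethod
    def load(cls, path: str | Path) -> "MultiHeadModel":
        with np.load(path, allow_pickle=False) as npz:
            header = json.loads(str(npz["header"]))
            weights = npz["weights"]
            bias = npz["bias"]
        cfg = dict(header["config"])
        cfg["ngram_range"] = tuple(cfg["ngram_range"])
        return cls(
            config=EncoderConfig(**cfg),
            schema=LabelSchema(header["schema"]["name"], tuple(header["schema"]["outcomes"])),
            weights=weights,
            bias=bias,
            meta=header["meta"],
        )


#: Schema used for scalar survival-risk models (a single regression head).
RISK_SCHEMA = LabelSchema("RISK_1", ("mortality_risk",))
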