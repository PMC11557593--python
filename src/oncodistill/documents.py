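"""Core document/label data model, corpus I/O, inclusion filters, truncation,
and patient-level cohort splitting.

The data model is deliberately small: a :class:`Document` is one clinical text
unit (an imaging report, an oncologist note, or a discharge summary) linked to
a patient and a site; labels are binary outcome vectors under a fixed
:class:`LabelSchema`; cohorts are always split at the patient level so that no
patient contributes documents to more than one of train/tune/test.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files (bad JSONL lines, id collisions)."""


class ConfigurationError(ValueError):
    """Raised for invalid configuration values."""


class SchemaMismatchError(ValueError):
    """Raised when a model and a request disagree on the label schema."""


# ---------------------------------------------------------------------------
# Label schemas
# ---------------------------------------------------------------------------

IMAGING_OUTCOMES: tuple[str, ...] = (
    "any_cancer",
    "progression",
    "response",
    "brain",
    "bone",
    "lung",
    "liver",
    "adrenal",
    "nodes",
    "peritoneum",
)

NOTE_OUTCOMES: tuple[str, ...] = ("any_cancer", "progression", "response")


@dataclass(frozen=True)
class LabelSchema:
    """An ordered, named set of binary outcomes.

    The order is fixed and stable across the whole pipeline: label matrices,
    logit tables and model heads all follow ``outcomes`` order.
    """

    name: str
    outcomes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.outcomes)) != len(self.outcomes):
            raise ConfigurationError("outcome names must be unique")
        if not self.outcomes:
            raise ConfigurationError("schema needs at least one outcome")

    def __len__(self) -> int:
        return len(self.outcomes)

    def index(self, outcome: str) -> int:
        try:
            return self.outcomes.index(outcome)
        except ValueError:
            raise SchemaMismatchError(
                f"outcome {outcome!r} not in schema {self.name}"
            ) from None


IMAGING_10 = LabelSchema("IMAGING_10", IMAGING_OUTCOMES)
NOTE_3 = LabelSchema("NOTE_3", NOTE_OUTCOMES)

_SCHEMAS = {s.name: s for s in (IMAGING_10, NOTE_3)}


def get_schema(name: str) -> LabelSchema:
    """Look up a built-in schema (``IMAGING_10`` or ``NOTE_3``) by name."""
    try:
        return _SCHEMAS[name]
    except KeyError:
        raise ConfigurationError(f"unknown label schema {name!r}") from None


# ---------------------------------------------------------------------------
# Documents
# ---------------------------------------------------------------------------

#: JSONL field names owned by Document itself; anything else round-trips
#: through ``extra``.
_DOC_FIELDS = ("doc_id", "patient_id", "site", "doc_type", "text", "timestamp", "origin")


@dataclass
class Document:
    """One clinical text unit with patient linkage and a site tag.

    ``origin`` records provenance for the privacy contract: ``"private"``
    documents must never enter a student's training path.
    """

    doc_id: str
    patient_id: str
    site: str
    doc_type: str  # {"imaging", "note", "discharge"}
    text: str
    timestamp: int | None = None
    origin: str = "unspecified"
    extra: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        rec = {
            "doc_id": self.doc_id,
            "patient_id": self.patient_id,
            "site": self.site,
            "doc_type": self.doc_type,
            "text": self.text,
            "origin": self.origin,
        }
        if self.timestamp is not None:
            rec["timestamp"] = self.timestamp
        rec.update(self.extra)
        return rec

    @classmethod
    def from_record(cls, rec: Mapping) -> "Document":
        if "doc_id" not in rec:
            raise CorpusFormatError("record missing doc_id")
        extra = {k: v for k, v in rec.items() if k not in _DOC_FIELDS}
        return cls(
            doc_id=str(rec["doc_id"]),
            patient_id=str(rec.get("patient_id", "")),
            site=str(rec.get("site", "")),
            doc_type=str(rec.get("doc_type", "imaging")),
            text=str(rec.get("text", "")),
            timestamp=rec.get("timestamp"),
            origin=str(rec.get("origin", "unspecified")),
            extra=extra,
        )


# ---------------------------------------------------------------------------
# Tokenization and truncation
# ---------------------------------------------------------------------------

_STRIP = string.punctuation


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip flanking punctuation.

    This is the pipeline's single tokenization: it feeds both the truncation
    policies and the hashed n-gram featurizer. Interior punctuation survives,
    so compounds like ``pet/ct`` remain one token.
    """
    out = []
    for tok in text.lower().split():
        tok = tok.strip(_STRIP)
        if tok:
            out.append(tok)
    return out


def truncate_tokens(
    text: str | Sequence[str], max_tokens: int, side: str = "keep_first"
) -> list[str]:
    """Truncate a document to at most ``max_tokens`` tokens.

    ``keep_first`` keeps the leading tokens (the imaging-report policy, which
    models a 512-token encoder limit); ``keep_last`` keeps the trailing tokens
    (left-truncation, the long-note policy at a 4096-token limit).
    """
    if max_tokens < 1:
        raise ValueError("max_tokens must be >= 1")
    if side not in ("keep_first", "keep_last"):
        raise ValueError(f"unknown truncation side {side!r}")
    tokens = tokenize(text) if isinstance(text, str) else list(text)
    if len(tokens) <= max_tokens:
        return tokens
    return tokens[:max_tokens] if side == "keep_first" else tokens[-max_tokens:]


#: Per-document-type truncation policy: (max_tokens, side).
TRUNCATION_POLICY: dict[str, tuple[int, str]] = {
    "imaging": (512, "keep_first"),
    "note": (4096, "keep_last"),
    "discharge": (4096, "keep_last"),
}


def prepare_tokens(doc: Document) -> list[str]:
    """Tokenize and truncate a document per its ``doc_type`` policy."""
    max_tokens, side = TRUNCATION_POLICY.get(doc.doc_type, (512, "keep_first"))
    return truncate_tokens(doc.text, max_tokens, side)


# ---------------------------------------------------------------------------
# Inclusion filters
# ---------------------------------------------------------------------------

# Disease terms match as case-folded substrings ("malignan" anchored to a
# token start, covering malignant/malignancy/...). Short modality strings
# (ct, mr, pet, nm) match only as delimiter-bounded tokens so that e.g.
# "eject" does not pass; "mammo" is long enough to match as a substring.
_MALIGNAN_RE = re.compile(r"\bmalignan")
_MODALITY_RE = re.compile(r"\b(?:ct|mr|pet|nm)\b")


def passes_imaging_filter(text: str) -> bool:
    """Inclusion rule for imaging/radiology reports in a public corpus.

    Requires a cancer term ("cancer", "restaging", or a token starting with
    "malignan") *and* a cancer-relevant modality (ct, mr, pet, nm as bounded
    tokens, or "mammo").
    """
    t = text.casefold()
    disease = "cancer" in t or "restaging" in t or _MALIGNAN_RE.search(t) is not None
    if not disease:
        return False
    return "mammo" in t or _MODALITY_RE.search(t) is not None


def passes_discharge_filter(text: str) -> bool:
    """Inclusion rule for discharge summaries: any cancer term suffices."""
    t = text.casefold()
    return "cancer" in t or _MALIGNAN_RE.search(t) is not None


FILTERS = {"imaging": passes_imaging_filter, "discharge": passes_discharge_filter}


# ---------------------------------------------------------------------------
# Patient-level cohort splitting
# ---------------------------------------------------------------------------

SPLIT_NAMES = ("train", "tune", "test")


@dataclass
class SplitAssignment:
    """A partition of patients into train / tune / test."""

    assignments: dict[str, str]

    def __getitem__(self, patient_id: str) -> str:
        return self.assignments[patient_id]

    def patients(self, split: str) -> list[str]:
        return [p for p, s in self.assignments.items() if s == split]

    def documents(self, docs: Iterable[Document], split: str) -> list[Document]:
        """All documents whose patient is assigned to ``split``."""
        return [d for d in docs if self.assignments.get(d.patient_id) == split]

    def sizes(self) -> dict[str, int]:
        out = {name: 0 for name in SPLIT_NAMES}
        for s in self.assignments.values():
            out[s] += 1
        return out


def split_cohort(
    patient_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.80, 0.10, 0.10),
    seed: int = 0,
) -> SplitAssignment:
    """Randomly partition patients into train/tune/test blocks.

    Patients are shuffled under ``seed`` and cut into contiguous blocks whose
    sizes come from largest-remainder rounding of ``fractions`` (ties broken
    toward the earlier split), so 10 patients at (0.8, 0.1, 0.1) give sizes
    (8, 1, 1) deterministically.
    """
    ids = list(patient_ids)
    if not ids:
        raise ConfigurationError("patient_ids must be nonempty")
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate patient IDs")
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or (fr <= 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ConfigurationError("fractions must be three positives summing to 1")

    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    raw = fr * n
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    for i in np.argsort(-remainder, kind="stable")[: n - sizes.sum()]:
        sizes[i] += 1

    mapping: dict[str, str] = {}
    start = 0
    for name, k in zip(SPLIT_NAMES, sizes):
        for pid in order[start : start + k]:
            mapping[pid] = name
        start += k
    return SplitAssignment(mapping)


# ---------------------------------------------------------------------------
# Corpus and table I/O
# ---------------------------------------------------------------------------


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    """Write a corpus as JSONL, one document record per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc.to_record(), sort_keys=True) + "\n")


def read_corpus(path: str | Path) -> list[Document]:
    """Read a JSONL corpus; errors name the offending line number."""
    path = Path(path)
    docs: list[Document] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                doc = Document.from_record(rec)
            except (json.JSONDecodeError, CorpusFormatError, TypeError) as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
            if doc.doc_id in seen:
                raise CorpusFormatError(f"line {lineno}: duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            docs.append(doc)
    return docs


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a doc_id-indexed table (labels, logits, survival) as CSV."""
    frame.to_csv(path, index_label="doc_id")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a doc_id-indexed CSV table."""
    frame = pd.read_csv(path)
    if "doc_id" not in frame.columns:
        raise CorpusFormatError("table is missing a doc_id column")
    if frame["doc_id"].duplicated().any():
        raise CorpusFormatError("duplicate doc_id in table")
    return frame.set_index("doc_id")


def labels_for(docs: Sequence[Document], labels: pd.DataFrame, schema: LabelSchema) -> np.ndarray:
    """Align a label table to a document list, returning an (n, K) 0/1 array."""
    missing = [d.doc_id for d in docs if d.doc_id not in labels.index]
    if missing:
        raise CorpusFormatError(f"labels missing for {len(missing)} documents, e.g. {missing[0]!r}")
    cols = [o for o in schema.outcomes]
    arr = labels.loc[[d.doc_id for d in docs], cols].to_numpy(dtype=float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    return arr
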