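"""Synthetic clinical-like corpus generator.

Real training data for outcome-extraction models (annotated imaging reports
and oncologist notes, plus a de-identified public corpus) are protected, so
this module generates corpora with the statistical structure the pipeline
assumes:

* multi-label outcome structure with gating — progression/response/metastatic
  site labels can be positive only when any-cancer is positive;
* lexical outcome cues with controllable fidelity (a positive label emits its
  cue phrase with probability ``cue_fidelity``; a negative label emits it
  spuriously with probability ``cue_noise``), plus an outcome-specific
  auxiliary context-token channel that mimics the diffuse wording signal real
  reports carry beyond a single key phrase;
* patient-unique identifier tokens in *private* documents only — the PHI
  analogue that an overfit model can memorize and a public-corpus student can
  never see;
* a site-style vocabulary shift (synonym substitution of a configurable
  fraction of the background/context vocabulary) emulating external
  validation at a second center; cue phrases are never substituted;
* filter-trigger strings at a controllable rate in public documents, so the
  inclusion filters pass a known fraction;
* censored survival times drawn per patient from an exponential
  proportional-hazards model with hazard ``lambda0 * exp(beta . labels)`` and
  independent uniform(0, C) censoring.

Identical config + seed reproduces a byte-identical corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .documents import (
    ConfigurationError,
    Document,
    LabelSchema,
    get_schema,
    write_corpus,
    write_table,
)

# ---------------------------------------------------------------------------
# Fixed lexical resources
# ---------------------------------------------------------------------------

# Seed for vocabulary construction only; the vocabulary is a fixed resource
# shared by every generator config so that two sites differ exactly by the
# site-shift substitution, never by the base word list.
_VOCAB_SEED = 74120413

_SYLLABLES = (
    "ar", "en", "ol", "ith", "um", "ex", "qu", "ost", "iv", "an",
    "er", "ud", "yn", "ob", "al", "ir", "et", "us", "om", "ak",
)

# Substrings that would interact with the inclusion filters; generated words
# and their synonyms are rejected if they contain any of these.
_FORBIDDEN = ("cancer", "restaging", "malignan", "mammo")

_BACKGROUND_SIZE = 400
_AUX_PER_OUTCOME = 12

#: Fixed multi-token cue phrasings per outcome — two interchangeable
#: variants, mirroring how different dictations word the same finding. Each
#: variant is emitted independently with probability ``cue_fidelity`` in a
#: positive document and ``cue_noise`` in a negative one. None contains a
#: filter trigger substring or a bounded modality token.
CUE_VARIANTS: dict[str, tuple[str, str]] = {
    "any_cancer": ("definite neoplasm burden", "tumor burden persists"),
    "progression": ("interval disease worsening", "worsening disease course"),
    "response": ("favorable treatment response", "marked therapeutic improvement"),
    "brain": ("new intraaxial lesion", "intraparenchymal metastatic focus"),
    "bone": ("osseous deposit seen", "skeletal lytic lesion"),
    "lung": ("pulmonary nodule growing", "pulmonary metastatic deposit"),
    "liver": ("hepatic lesion noted", "hepatic hypodense focus"),
    "adrenal": ("adrenal mass enlarging", "suprarenal nodular enlargement"),
    "nodes": ("nodal enlargement present", "lymphadenopathy newly apparent"),
    "peritoneum": ("peritoneal seeding suspected", "omental nodularity increasing"),
}

#: The primary cue phrase per outcome (first variant).
CUE_PHRASES: dict[str, str] = {o: v[0] for o, v in CUE_VARIANTS.items()}

#: Site-dialect paraphrase of each outcome's *second* cue variant. Under a
#: site shift s, a second-variant mention is dictated in the local dialect
#: with probability s; the primary phrasing is universal and never
#: substituted, which is what lets models transfer across sites at all.
CUE_DIALECT: dict[str, str] = {
    "any_cancer": "neoplastic load evident",
    "progression": "advancing disease trajectory",
    "response": "notable regression achieved",
    "brain": "cerebral metastatic deposit",
    "bone": "bony destructive focus",
    "lung": "airspace metastatic nodule",
    "liver": "liver hypoattenuating lesion",
    "adrenal": "adrenal nodular prominence",
    "nodes": "enlarged nodal stations",
    "peritoneum": "serosal implant burden",
}

#: Filter-trigger phrases by public document mode. Imaging triggers satisfy
#: both the disease-term and the modality requirement of the imaging filter.
TRIGGER_PHRASES: dict[str, tuple[str, ...]] = {
    "imaging": (
        "restaging ct thorax",
        "pet restaging survey",
        "restaging mr abdomen",
        "nm restaging scan",
    ),
    "discharge": (
        "history of cancer reviewed",
        "prior malignant disease noted",
    ),
}

CANCER_TYPES = ("nsclc", "crc", "breast", "pancreas", "prostate")

# A truly positive document that mentions its cue tends to mention it more
# than once; a spurious mention in a negative document appears exactly once.
_CUE_MAX_REPEATS = 3




def _make_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    words: list[str] = []
    while len(words) < n:
        k = int(rng.integers(3, 5))
        w = "".join(rng.choice(_SYLLABLES) for _ in range(k))
        if w in taken or any(f in w for f in _FORBIDDEN):
            continue
        taken.add(w)
        words.append(w)
    return words


@lru_cache(maxsize=1)
def _base_vocabulary() -> tuple[tuple[str, ...], dict[str, tuple[str, ...]], tuple[str, ...]]:
    """(background words, aux words per outcome, shift order).

    ``shift order`` is a fixed permutation of all substitutable words; a site
    shift of s replaces the first ceil(s * V) of them with synonyms, so the
    shifted subset is nested across shift levels and identical between runs.
    """
    rng = np.random.default_rng(_VOCAB_SEED)
    taken: set[str] = set()
    background = tuple(_make_words(rng, _BACKGROUND_SIZE, taken))
    aux = {
        outcome: tuple(_make_words(rng, _AUX_PER_OUTCOME, taken))
        for outcome in CUE_PHRASES
    }
    substitutable = list(background) + [w for ws in aux.values() for w in ws]
    order = tuple(
        substitutable[i] for i in np.random.default_rng(_VOCAB_SEED + 1).permutation(len(substitutable))
    )
    return background, aux, order


def _synonym(word: str) -> str:
    syn = word[::-1] + "yl"
    if any(f in syn for f in _FORBIDDEN):  # pragma: no cover - defensive
        syn = word + "plex"
    return syn


def _site_lexicon(site_shift: float) -> dict[str, str]:
    """Word -> site-specific word map at the given shift level."""
    background, aux, order = _base_vocabulary()
    n_shift = int(np.ceil(site_shift * len(order)))
    shifted = set(order[:n_shift])
    mapping = {}
    for w in list(background) + [w for ws in aux.values() for w in ws]:
        mapping[w] = _synonym(w) if w in shifted else w
    return mapping


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Default outcome probabilities. ``any_cancer`` is marginal; every gated
#: outcome's value is the probability *conditional on any_cancer = 1*.
DEFAULT_PREVALENCE: dict[str, float] = {
    "any_cancer": 0.60,
    "progression": 0.40,
    "response": 0.25,
    "brain": 0.10,
    "bone": 0.25,
    "lung": 0.20,
    "liver": 0.20,
    "adrenal": 0.08,
    "nodes": 0.30,
    "peritoneum": 0.10,
}

#: Default per-outcome log hazard ratios for the survival simulation
#: (time unit: months). Progressive/metastatic disease raises the hazard;
#: treatment response lowers it.
DEFAULT_HAZARD_COEFS: dict[str, float] = {
    "any_cancer": 1.5,
    "progression": 1.2,
    "response": -1.0,
    "brain": 1.0,
    "bone": 0.6,
    "lung": 0.6,
    "liver": 0.8,
    "adrenal": 0.4,
    "nodes": 0.4,
    "peritoneum": 0.6,
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-corpus simulation.

    ``prevalence`` and ``hazard_coefs`` may be partial mappings; unlisted
    outcomes fall back to the module defaults. ``id_mentions`` bounds the
    number of patient-identifier mentions per private document (names and
    record numbers recur throughout real clinical text; long-form notes are
    far denser in identifiers than imaging reports).
    """

    schema_name: str = "IMAGING_10"
    n_patients: int = 1000
    docs_per_patient: int | tuple[int, int] = 2
    prevalence: dict[str, float] = field(default_factory=dict)
    cue_fidelity: float = 0.9
    cue_noise: float = 0.05
    aux_rate_pos: float = 3.5
    aux_rate_neg: float = 0.15
    id_mentions: tuple[int, int] = (2, 4)
    site_shift: float = 0.0
    site: str = "siteA"
    filter_trigger_rate: float = 0.9
    hazard_baseline: float = 0.02
    hazard_coefs: dict[str, float] = field(default_factory=dict)
    censor_horizon: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        get_schema(self.schema_name)  # raises for unknown schema
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        probs = {
            "cue_fidelity": self.cue_fidelity,
            "cue_noise": self.cue_noise,
            "site_shift": self.site_shift,
            "filter_trigger_rate": self.filter_trigger_rate,
            **{f"prevalence[{k}]": v for k, v in self.prevalence.items()},
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.aux_rate_pos < 0 or self.aux_rate_neg < 0:
            raise ConfigurationError("auxiliary context rates must be >= 0")
        if isinstance(self.id_mentions, list):
            self.id_mentions = tuple(self.id_mentions)
        lo_id, hi_id = self.id_mentions
        if lo_id < 0 or hi_id < lo_id:
            raise ConfigurationError("id_mentions range must satisfy 0 <= lo <= hi")
        if self.hazard_baseline <= 0:
            raise ConfigurationError("hazard_baseline must be > 0")
        if self.censor_horizon <= 0:
            raise ConfigurationError("censor_horizon must be > 0")
        if isinstance(self.docs_per_patient, (tuple, list)):
            lo, hi = self.docs_per_patient
            if lo < 1 or hi < lo:
                raise ConfigurationError("docs_per_patient range must satisfy 1 <= lo <= hi")
        elif self.docs_per_patient < 1:
            raise ConfigurationError("docs_per_patient must be >= 1")

    @property
    def schema(self) -> LabelSchema:
        return get_schema(self.schema_name)

    def outcome_prevalence(self, outcome: str) -> float:
        return float(self.prevalence.get(outcome, DEFAULT_PREVALENCE[outcome]))

    def outcome_hazard_coef(self, outcome: str) -> float:
        return float(self.hazard_coefs.get(outcome, DEFAULT_HAZARD_COEFS[outcome]))

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("docs_per_patient", "id_mentions"):
            if isinstance(d[key], tuple):
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        for key in ("docs_per_patient", "id_mentions"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from a YAML or JSON file."""
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Corpus containers
# ---------------------------------------------------------------------------


@dataclass
class LabeledCorpus:
    """A labeled private-style corpus: documents, labels and survival."""

    documents: list[Document]
    labels: pd.DataFrame  # index doc_id, one 0/1 column per outcome
    survival: pd.DataFrame  # index doc_id: patient_id, time, event
    schema: LabelSchema

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_corpus(self.documents, directory / "corpus.jsonl")
        write_table(self.labels, directory / "labels.csv")
        write_table(self.survival, directory / "survival.csv")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _draw_labels(rng: np.random.Generator, config: GeneratorConfig) -> dict[str, int]:
    schema = config.schema
    y_cancer = int(rng.random() < config.outcome_prevalence("any_cancer"))
    labels = {"any_cancer": y_cancer}
    for outcome in schema.outcomes[1:]:
        if y_cancer:
            labels[outcome] = int(rng.random() < config.outcome_prevalence(outcome))
        else:
            labels[outcome] = 0  # gating: no cancer, no downstream outcome
    return labels


def _compose_text(
    rng: np.random.Generator,
    config: GeneratorConfig,
    labels: Mapping[str, int],
    lexicon: Mapping[str, str],
    id_token: str | None,
    trigger: str | None,
) -> str:
    background, aux_vocab, _ = _base_vocabulary()
    n_bg = int(rng.integers(60, 120))
    bg_idx = rng.integers(0, len(background), size=n_bg)
    # segments: inserted chunks are atomic, so a cue phrase is never split
    # by a later insertion and phrase containment matches the emission law
    segments: list[list[str]] = [[lexicon[background[i]]] for i in bg_idx]

    inserts: list[list[str]] = []
    for outcome in config.schema.outcomes:
        y = labels[outcome]
        p_cue = config.cue_fidelity if y else config.cue_noise
        for vi, variant in enumerate(CUE_VARIANTS[outcome]):
            if rng.random() < p_cue:
                phrase = variant
                if vi == 1 and rng.random() < config.site_shift:
                    phrase = CUE_DIALECT[outcome]
                reps = int(rng.integers(1, _CUE_MAX_REPEATS + 1)) if y else 1
                for _ in range(reps):
                    inserts.append(phrase.split())
        rate = config.aux_rate_pos if y else config.aux_rate_neg
        n_aux = int(rng.poisson(rate))
        if n_aux:
            words = aux_vocab[outcome]
            picks = rng.integers(0, len(words), size=n_aux)
            inserts.append([lexicon[words[i]] for i in picks])
    if trigger is not None:
        inserts.append(trigger.split())
    if id_token is not None:
        lo_id, hi_id = config.id_mentions
        inserts.extend([[id_token]] * int(rng.integers(lo_id, hi_id + 1)))

    for chunk in inserts:
        pos = int(rng.integers(0, len(segments) + 1))
        segments.insert(pos, chunk)
    return " ".join(tok for seg in segments for tok in seg)


def _private_doc_type(schema: LabelSchema) -> str:
    return "imaging" if schema.name == "IMAGING_10" else "note"


def _public_doc_type(schema: LabelSchema) -> str:
    return "imaging" if schema.name == "IMAGING_10" else "discharge"


def generate_labeled_corpus(config: GeneratorConfig) -> LabeledCorpus:
    """Generate a labeled private-style corpus.

    Labels are drawn once per patient (root Bernoulli for any-cancer,
    conditional Bernoullis for the gated outcomes) and shared by all of the
    patient's documents; survival is simulated at the patient level from an
    exponential distribution with hazard ``lambda0 * exp(beta . labels)``,
    censored at an independent uniform(0, C) draw. Every private document
    embeds patient-unique identifier tokens — the PHI analogue.
    """
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    lexicon = _site_lexicon(config.site_shift)
    doc_type = _private_doc_type(schema)

    documents: list[Document] = []
    label_rows: list[dict] = []
    surv_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"{config.site.lower()}-p{i:05d}"
        cancer_type = CANCER_TYPES[int(rng.integers(0, len(CANCER_TYPES)))]
        labels = _draw_labels(rng, config)

        log_hr = sum(
            config.outcome_hazard_coef(o) * labels[o] for o in schema.outcomes
        )
        lam = config.hazard_baseline * float(np.exp(log_hr))
        t_event = float(rng.exponential(1.0 / lam))
        t_censor = float(rng.uniform(0.0, config.censor_horizon))
        time = min(t_event, t_censor)
        event = int(t_event <= t_censor)

        if isinstance(config.docs_per_patient, (tuple, list)):
            lo, hi = config.docs_per_patient
            n_docs = int(rng.integers(lo, hi + 1))
        else:
            n_docs = int(config.docs_per_patient)

        id_token = f"zz{pid.replace('-', '')}zz"
        for j in range(n_docs):
            doc_id = f"{pid}-d{j}"
            text = _compose_text(rng, config, labels, lexicon, id_token, trigger=None)
            documents.append(
                Document(
                    doc_id=doc_id,
                    patient_id=pid,
                    site=config.site,
                    doc_type=doc_type,
                    text=text,
                    timestamp=j,
                    origin="private",
                    extra={"cancer_type": cancer_type},
                )
            )
            label_rows.append({"doc_id": doc_id, **labels})
            surv_rows.append(
                {"doc_id": doc_id, "patient_id": pid, "time": time, "event": event}
            )

    label_cols = list(schema.outcomes)
    labels_df = pd.DataFrame(label_rows, columns=["doc_id"] + label_cols)
    labels_df = labels_df.set_index("doc_id") if len(labels_df) else pd.DataFrame(
        columns=label_cols, index=pd.Index([], name="doc_id")
    )
    surv_df = pd.DataFrame(surv_rows, columns=["doc_id", "patient_id", "time", "event"])
    surv_df = surv_df.set_index("doc_id") if len(surv_df) else pd.DataFrame(
        columns=["patient_id", "time", "event"], index=pd.Index([], name="doc_id")
    )
    return LabeledCorpus(documents, labels_df, surv_df, schema)


def generate_public_corpus(config: GeneratorConfig, n_docs: int) -> list[Document]:
    """Generate an unlabeled public-style corpus (one synthetic patient per
    document, no linkage to any labeled corpus, no identifier tokens).

    Each document carries a filter-trigger phrase with probability
    ``filter_trigger_rate``; latent outcome labels drive cue emission exactly
    as in the private corpus but are never returned — like a de-identified
    public dataset, the text describes outcomes without gold annotations.
    """
    if n_docs < 0:
        raise ConfigurationError("n_docs must be >= 0")
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    lexicon = _site_lexicon(config.site_shift)
    doc_type = _public_doc_type(schema)
    trigger_mode = "imaging" if doc_type == "imaging" else "discharge"
    triggers = TRIGGER_PHRASES[trigger_mode]

    documents: list[Document] = []
    for i in range(n_docs):
        labels = _draw_labels(rng, config)
        trigger = None
        if rng.random() < config.filter_trigger_rate:
            trigger = triggers[int(rng.integers(0, len(triggers)))]
        text = _compose_text(rng, config, labels, lexicon, id_token=None, trigger=trigger)
        documents.append(
            Document(
                doc_id=f"pub-d{i:06d}",
                patient_id=f"pub-p{i:06d}",
                site="public",
                doc_type=doc_type,
                text=text,
                origin="public",
            )
        )
    return documents
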