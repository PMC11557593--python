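"""Teacher and student training procedures.

Teachers are trained with per-head binary cross entropy on private labeled
documents. Teachers then soft-label a filtered public corpus with their
predicted log odds (logits), and students — freshly initialized, same
architecture — are trained on the public text alone to match those logits
under a mean-squared-error loss (logit-matching distillation). A hard-label
variant trains the student with BCE on assigned binary labels instead (the
mechanics of using an external labeler such as an LLM as the teacher).

The survival arm replaces the classification heads with a single risk head:
the teacher minimizes an exponential proportional-hazards negative
log-likelihood that accommodates right-censoring, and the student regresses
onto the teacher's scalar risk scores.

A privacy contract runs through the student path: documents whose provenance
is ``private`` may never appear among a student's training inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .documents import ConfigurationError, Document, LabelSchema, labels_for
from .encoder import (
    EncoderConfig,
    MultiHeadModel,
    RISK_SCHEMA,
    featurize_documents,
)

logger = logging.getLogger(__name__)


class PrivacyContractError(RuntimeError):
    """Raised when private documents reach a student training path."""


class CohortOverlapError(ValueError):
    """Raised when patients leak between training and tuning sets."""


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def _as_2d(a) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def bce_multilabel_loss(logits, labels) -> float:
    """Mean over documents of the summed per-head binary cross entropy.

    Computed in the numerically stable form
    ``max(z, 0) - z*y + log(1 + exp(-|z|))``, so saturated logits neither
    overflow nor lose precision.
    """
    z = _as_2d(logits)
    y = _as_2d(labels)
    if z.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {z.shape} vs labels {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(per.sum(axis=1).mean())


def mse_distill_loss(student_logits, teacher_logits) -> float:
    """Mean over documents and heads of the squared logit difference."""
    s = _as_2d(student_logits)
    t = _as_2d(teacher_logits)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: student {s.shape} vs teacher {t.shape}")
    return float(np.mean((s - t) ** 2))


def survival_nll(risk, time, event) -> float:
    """Exponential proportional-hazards negative log-likelihood.

    With per-document log relative hazard eta, follow-up time t >= 0 and
    event indicator d (1 = death observed), the mean over documents of
    ``exp(eta) * t - d * eta``: the cumulative hazard accrues for everyone,
    the log-hazard term only for observed events.
    """
    eta = np.asarray(risk, dtype=float).ravel()
    t = np.asarray(time, dtype=float).ravel()
    d = np.asarray(event, dtype=float).ravel()
    if not (eta.shape == t.shape == d.shape):
        raise ValueError("risk, time and event must share shape")
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    if not np.isin(d, (0.0, 1.0)).all():
        raise ValueError("event indicator must be binary 0/1")
    return float(np.mean(np.exp(eta) * t - d * eta))


# ---------------------------------------------------------------------------
# Training configuration and the shared gradient-descent core
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Mini-batch gradient-descent settings (deterministic given ``seed``).

    ``early_stop_metric`` selects the returned model state: ``tune_loss``
    keeps the epoch with the best tuning-set loss, ``tune_auroc`` the epoch
    with the best mean tuning-set discrimination, ``none`` the final epoch.
    """

    learning_rate: float = 0.5
    epochs: int = 40
    batch_size: int = 256
    weight_decay: float = 1e-4
    seed: int = 0
    early_stop_metric: str = "tune_loss"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("learning_rate, epochs and batch_size must be positive")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be >= 0")
        if self.early_stop_metric not in ("tune_loss", "tune_auroc", "none"):
            raise ConfigurationError(f"unknown early_stop_metric {self.early_stop_metric!r}")


def _mean_tune_auroc(Z: np.ndarray, Y: np.ndarray) -> float:
    if not np.isfinite(Z).all():
        return float("-inf")  # a diverged state is never selected
    vals = []
    for k in range(Y.shape[1]):
        y = Y[:, k]
        if 0 < y.sum() < len(y):
            vals.append(roc_auc_score(y, Z[:, k]))
    return float(np.mean(vals)) if vals else 0.5


# Clip the log-hazard inside exp() so a mid-training excursion cannot
# overflow; the bound is far outside the realistic risk range.
_ETA_CLIP = 30.0


def _fit_linear(
    X: sp.csr_matrix,
    targets,
    mode: str,
    config: TrainConfig,
    n_heads: int,
    tune: tuple[sp.csr_matrix, np.ndarray] | None = None,
    init_bias: np.ndarray | None = None,
    stop_train_loss: float | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Gradient-descent core shared by every training procedure.

    ``mode`` is one of ``bce`` (targets: binary labels), ``mse`` (targets:
    logits) or ``survival`` (targets: (time, event) pair, single head).
    Returns (weights, bias, meta) where meta records the loss trace and the
    selected epoch.
    """
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    W = np.zeros((X.shape[1], n_heads))
    b = np.zeros(n_heads) if init_bias is None else np.array(init_bias, dtype=float)

    if mode == "survival":
        t_all, d_all = targets
        t_all = np.asarray(t_all, dtype=float)
        d_all = np.asarray(d_all, dtype=float)
    else:
        Y_all = _as_2d(targets)

    def full_loss() -> float:
        Z = np.asarray(X @ W) + b
        if mode == "bce":
            return bce_multilabel_loss(Z, Y_all)
        if mode == "mse":
            return mse_distill_loss(Z, Y_all)
        return survival_nll(Z[:, 0], t_all, d_all)

    trace: list[float] = []
    tune_trace: list[float] = []
    best = None  # (criterion value, W, b, epoch); lower is better

    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            Xb = X[idx]
            nb = len(idx)
            Z = np.asarray(Xb @ W) + b
            if mode == "bce":
                G = (expit(Z) - Y_all[idx]) / nb
            elif mode == "mse":
                G = 2.0 * (Z - Y_all[idx]) / (nb * n_heads)
            else:
                lam = np.exp(np.clip(Z[:, 0], -_ETA_CLIP, _ETA_CLIP))
                G = ((lam * t_all[idx] - d_all[idx]) / nb)[:, None]
            W -= config.learning_rate * (np.asarray(Xb.T @ G) + config.weight_decay * W)
            b -= config.learning_rate * G.sum(axis=0)

        loss = full_loss()
        trace.append(loss)

        criterion = None
        if tune is not None and config.early_stop_metric != "none":
            Xt, Yt = tune
            Zt = np.asarray(Xt @ W) + b
            if config.early_stop_metric == "tune_loss":
                criterion = (
                    bce_multilabel_loss(Zt, Yt) if mode == "bce" else mse_distill_loss(Zt, Yt)
                )
            else:  # tune_auroc: negate so that lower is better
                criterion = -_mean_tune_auroc(Zt, Yt)
            tune_trace.append(criterion)
            if best is None or criterion < best[0]:
                best = (criterion, W.copy(), b.copy(), epoch)

        if stop_train_loss is not None and loss < stop_train_loss:
            break

    if best is not None:
        _, W, b, selected = best
    else:
        selected = len(trace) - 1

    meta = {
        "mode": mode,
        "train_config": asdict(config),
        "loss_trace": trace,
        "tune_trace": tune_trace,
        "selected_epoch": int(selected),
        "epochs_run": len(trace),
    }
    return W, b, meta


def _check_patient_disjoint(a: Sequence[Document], b: Sequence[Document], what: str) -> None:
    overlap = {d.patient_id for d in a} & {d.patient_id for d in b}
    if overlap:
        raise CohortOverlapError(
            f"{len(overlap)} patients appear in both {what}, e.g. {sorted(overlap)[0]!r}"
        )


def _check_public_only(docs: Sequence[Document]) -> None:
    private = [d.doc_id for d in docs if d.origin == "private"]
    if private:
        raise PrivacyContractError(
            f"{len(private)} private documents in a student training path, "
            f"e.g. {private[0]!r}"
        )


# ---------------------------------------------------------------------------
# Teachers
# ---------------------------------------------------------------------------


def train_teacher(
    train_docs: Sequence[Document],
    train_labels: pd.DataFrame,
    tune_docs: Sequence[Document],
    tune_labels: pd.DataFrame,
    schema: LabelSchema,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
) -> MultiHeadModel:
    """Train a multi-head teacher on private labeled documents (BCE loss).

    Training and tuning documents must be patient-disjoint; the returned
    state is the epoch with the best tuning-set loss when early stopping is
    on.
    """
    encoder_config = encoder_config or EncoderConfig()
    train_config = train_config or TrainConfig()
    _check_patient_disjoint(train_docs, tune_docs, "train and tune sets")

    X = featurize_documents(train_docs, encoder_config)
    Y = labels_for(train_docs, train_labels, schema)
    Xt = featurize_documents(tune_docs, encoder_config)
    Yt = labels_for(tune_docs, tune_labels, schema)

    W, b, meta = _fit_linear(X, Y, "bce", train_config, len(schema), tune=(Xt, Yt))
    meta["role"] = "teacher"
    meta["training_provenance"] = "private"
    return MultiHeadModel(encoder_config, schema, W, b, meta)


def soft_label_public(
    teacher: MultiHeadModel,
    public_docs: Sequence[Document],
    doc_filter: Callable[[str], bool],
) -> pd.DataFrame:
    """Run teacher inference on the public documents passing ``doc_filter``.

    Returns a doc_id-indexed logit table with one column per teacher outcome;
    only passing documents are labeled.
    """
    passing = [d for d in public_docs if doc_filter(d.text)]
    if not passing:
        return pd.DataFrame(
            columns=list(teacher.schema.outcomes), index=pd.Index([], name="doc_id")
        )
    return teacher.predict_logits(passing)


# ---------------------------------------------------------------------------
# Students
# ---------------------------------------------------------------------------


def _fresh_student_encoder(encoder_config: EncoderConfig, train_config: TrainConfig) -> EncoderConfig:
    """Students are freshly initialized: they share the teacher's
    architecture (feature width, n-gram orders) but draw a fresh hashing
    seed — the hashing-trick analogue of fresh weight initialization. This
    also severs any collision path from public n-grams into buckets a
    teacher used to memorize private-only tokens."""
    import dataclasses

    return dataclasses.replace(
        encoder_config, hash_seed=encoder_config.hash_seed + 7919 * (train_config.seed + 1)
    )


def _student_inputs(
    public_docs: Sequence[Document], table: pd.DataFrame
) -> tuple[list[Document], np.ndarray]:
    _check_public_only(public_docs)
    docs = [d for d in public_docs if d.doc_id in table.index]
    if not docs:
        raise ValueError("no public training documents with targets")
    targets = table.loc[[d.doc_id for d in docs]].to_numpy(dtype=float)
    return docs, targets


def train_student(
    public_docs: Sequence[Document],
    teacher_logits: pd.DataFrame,
    tune_docs: Sequence[Document],
    tune_labels: pd.DataFrame,
    schema: LabelSchema,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
) -> MultiHeadModel:
    """Train a student on public text to match teacher logits (MSE loss).

    The student is freshly initialized and never sees private document text;
    the private tuning split is used only for model selection (best mean
    tuning-set AUROC by default). Passing any private document as a training
    input raises :class:`PrivacyContractError`.
    """
    encoder_config = encoder_config or EncoderConfig()
    train_config = train_config or TrainConfig(
        learning_rate=0.05, epochs=60, early_stop_metric="tune_auroc"
    )
    encoder_config = _fresh_student_encoder(encoder_config, train_config)
    docs, T = _student_inputs(public_docs, teacher_logits[list(schema.outcomes)])

    X = featurize_documents(docs, encoder_config)
    tune = None
    if tune_docs:
        Xt = featurize_documents(tune_docs, encoder_config)
        Yt = labels_for(tune_docs, tune_labels, schema)
        tune = (Xt, Yt)
        if train_config.early_stop_metric == "tune_loss":
            # tune-set loss against *labels* is not defined for a logit
            # regression; selection uses discrimination instead.
            train_config = TrainConfig(**{**asdict(train_config), "early_stop_metric": "tune_auroc"})

    W, b, meta = _fit_linear(X, T, "mse", train_config, len(schema), tune=tune)
    meta["role"] = "student"
    meta["training_provenance"] = "public"
    meta["distillation"] = "soft_logit_mse"
    return MultiHeadModel(encoder_config, schema, W, b, meta)


def train_student_hard(
    public_docs: Sequence[Document],
    assigned_labels: pd.DataFrame,
    schema: LabelSchema,
    tune_docs: Sequence[Document] = (),
    tune_labels: pd.DataFrame | None = None,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
) -> MultiHeadModel:
    """Train a hard-label student with BCE on assigned binary labels."""
    encoder_config = encoder_config or EncoderConfig()
    train_config = train_config or TrainConfig(
        learning_rate=0.5, epochs=60, early_stop_metric="tune_auroc"
    )
    encoder_config = _fresh_student_encoder(encoder_config, train_config)
    docs, Y = _student_inputs(public_docs, assigned_labels[list(schema.outcomes)])
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("assigned labels must be binary 0/1")

    X = featurize_documents(docs, encoder_config)
    tune = None
    if tune_docs:
        Xt = featurize_documents(tune_docs, encoder_config)
        Yt = labels_for(tune_docs, tune_labels, schema)
        tune = (Xt, Yt)

    W, b, meta = _fit_linear(X, Y, "bce", train_config, len(schema), tune=tune)
    meta["role"] = "student"
    meta["training_provenance"] = "public"
    meta["distillation"] = "hard_label_bce"
    return MultiHeadModel(encoder_config, schema, W, b, meta)


# ---------------------------------------------------------------------------
# Survival arm
# ---------------------------------------------------------------------------


def train_survival_teacher(
    train_docs: Sequence[Document],
    survival: pd.DataFrame,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
) -> MultiHeadModel:
    """Train a survival teacher: one scalar risk head minimizing the
    censored exponential proportional-hazards NLL.

    ``survival`` is a doc_id-indexed table with ``time`` and ``event``
    columns. The intercept is initialized at the constant-hazard MLE
    ``log(sum(events) / sum(time))`` so early gradients are well-scaled.
    """
    encoder_config = encoder_config or EncoderConfig()
    # the exponential NLL is step-sensitive (exp of the linear predictor);
    # the stable step size is well below the classification teacher's.
    train_config = train_config or TrainConfig(
        learning_rate=0.003, epochs=200, weight_decay=1e-4, early_stop_metric="none"
    )
    X = featurize_documents(train_docs, encoder_config)
    sub = survival.loc[[d.doc_id for d in train_docs]]
    t = sub["time"].to_numpy(dtype=float)
    d = sub["event"].to_numpy(dtype=float)
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    total_events = d.sum()
    init_b = np.array([np.log(max(total_events, 1.0) / max(t.sum(), 1e-12))])

    W, b, meta = _fit_linear(
        X, (t, d), "survival", train_config, 1, init_bias=init_b
    )
    meta["role"] = "survival_teacher"
    meta["training_provenance"] = "private"
    return MultiHeadModel(encoder_config, RISK_SCHEMA, W, b, meta)


def train_survival_student(
    public_docs: Sequence[Document],
    teacher_risks: pd.DataFrame,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
) -> MultiHeadModel:
    """Train a survival student regressing onto teacher risk scores (MSE)."""
    encoder_config = encoder_config or EncoderConfig()
    # single-head MSE: gradients are not damped by the 1/K head average,
    # so the stable step size is an order of magnitude below the
    # classification student's.
    train_config = train_config or TrainConfig(
        learning_rate=0.005, epochs=80, early_stop_metric="none"
    )
    encoder_config = _fresh_student_encoder(encoder_config, train_config)
    docs, T = _student_inputs(public_docs, teacher_risks[list(RISK_SCHEMA.outcomes)])
    X = featurize_documents(docs, encoder_config)
    W, b, meta = _fit_linear(X, T, "mse", train_config, 1)
    meta["role"] = "survival_student"
    meta["training_provenance"] = "public"
    meta["distillation"] = "soft_risk_mse"
    return MultiHeadModel(encoder_config, RISK_SCHEMA, W, b, meta)
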