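"""Membership-inference attack (MIA) audit of teacher and student models.

The audit demonstrates the privacy asymmetry that motivates distillation:
a teacher deliberately overfit to a small set of private "member" notes
leaks membership — a simple logistic-regression attack, given a note's true
labels and the teacher's logits for it, can tell members from patient-
disjoint nonmembers. A student trained only on a public corpus soft-labeled
by that same overfit teacher cannot reproduce the memorized, member-specific
logit component (those features never occur in public text), so the same
attack on the student's outputs collapses toward chance and the student's
logit dispersion collapses relative to the teacher's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .documents import Document, LabelSchema, labels_for, passes_discharge_filter
from .distillation import (
    CohortOverlapError,
    TrainConfig,
    _fit_linear,
    soft_label_public,
    train_student,
)
from .encoder import EncoderConfig, MultiHeadModel, featurize_documents
from .evaluation import auroc, bootstrap_ci


class OverfitWarning(UserWarning):
    """Emitted when a deliberately-overfit model misses its target loss."""


# ---------------------------------------------------------------------------
# Overfit teacher
# ---------------------------------------------------------------------------


def overfit_teacher(
    member_docs: Sequence[Document],
    member_labels: pd.DataFrame,
    schema: LabelSchema,
    encoder_config: EncoderConfig | None = None,
    learning_rate: float = 1.0,
    max_epochs: int = 4000,
    target_loss: float = 1e-3,
    weight_decay: float = 0.0,
    seed: int = 0,
) -> MultiHeadModel:
    """Train a teacher to memorize a small member set.

    No early stopping and (by default) no weight decay; full-batch gradient
    descent runs
    until the training loss drops below ``target_loss`` or ``max_epochs`` is
    reached. The final training loss and accuracy are recorded in
    ``meta["overfit"]`` as evidence of memorization; a warning (not an
    error) is emitted if the overfit criterion is not met.
    """
    encoder_config = encoder_config or EncoderConfig()
    X = featurize_documents(member_docs, encoder_config)
    Y = labels_for(member_docs, member_labels, schema)
    cfg = TrainConfig(
        learning_rate=learning_rate,
        epochs=max_epochs,
        batch_size=max(len(member_docs), 1),
        weight_decay=weight_decay,
        seed=seed,
        early_stop_metric="none",
    )
    W, b, meta = _fit_linear(X, Y, "bce", cfg, len(schema), stop_train_loss=target_loss)

    Z = np.asarray(X @ W) + b
    final_loss = meta["loss_trace"][-1]
    train_acc = float(((Z > 0) == (Y > 0.5)).mean())
    achieved = final_loss < target_loss
    meta["role"] = "overfit_teacher"
    meta["training_provenance"] = "private"
    meta["overfit"] = {
        "final_train_loss": final_loss,
        "train_accuracy": train_acc,
        "target_loss": target_loss,
        "achieved": bool(achieved),
        "n_members": len(member_docs),
    }
    if not achieved:
        warnings.warn(
            f"overfit criterion not met: train loss {final_loss:.3g} >= {target_loss:g}",
            OverfitWarning,
        )
    return MultiHeadModel(encoder_config, schema, W, b, meta)


# ---------------------------------------------------------------------------
# Attack dataset and attack model
# ---------------------------------------------------------------------------


def build_attack_dataset(
    model: MultiHeadModel,
    member_docs: Sequence[Document],
    nonmember_docs: Sequence[Document],
    member_labels: pd.DataFrame,
    nonmember_labels: pd.DataFrame,
    train_frac: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble per-document attack records.

    Features are the true label vector concatenated with the model's logit
    vector. Records are split into attack_train / attack_eval at
    ``train_frac``, stratified by membership so both classes appear in both
    splits. Member and nonmember sets must be patient-disjoint.
    """
    if not member_docs or not nonmember_docs:
        raise ValueError("member and nonmember sets must both be nonempty")
    overlap = {d.patient_id for d in member_docs} & {d.patient_id for d in nonmember_docs}
    if overlap:
        raise CohortOverlapError(
            f"{len(overlap)} patients in both member and nonmember sets"
        )
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")

    schema = model.schema
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for membership, docs, labels in (
        (1, member_docs, member_labels),
        (0, nonmember_docs, nonmember_labels),
    ):
        logits = model.predict_logits(docs)
        Y = labels_for(docs, labels, schema)
        n = len(docs)
        n_train = int(round(train_frac * n))
        order = rng.permutation(n)
        split_of = {}
        for rank, i in enumerate(order):
            split_of[i] = "attack_train" if rank < n_train else "attack_eval"
        for i, doc in enumerate(docs):
            row = {"doc_id": doc.doc_id, "membership": membership, "split": split_of[i]}
            for j, o in enumerate(schema.outcomes):
                row[f"label_{o}"] = Y[i, j]
            for o in schema.outcomes:
                row[f"logit_{o}"] = logits.at[doc.doc_id, o]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AttackResult:
    """Outcome of a membership-inference attack."""

    auroc: float
    ci_low: float
    ci_high: float
    n_train: int
    n_eval: int


def run_attack(
    records: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> AttackResult:
    """Fit the logistic-regression attack on attack_train and score its
    membership AUROC (with 95% bootstrap CI) on attack_eval.

    The attack model is a plain (unpenalized) logistic regression on
    standardized features, with a small-ridge fallback when the unpenalized
    fit fails to converge (the attack features can be linearly separable).
    """
    feature_cols = [c for c in records.columns if c.startswith(("label_", "logit_"))]
    train = records[records["split"] == "attack_train"]
    evl = records[records["split"] == "attack_eval"]
    for name, part in (("train", train), ("eval", evl)):
        if part["membership"].nunique() < 2:
            raise ValueError(f"attack_{name} split contains a single membership class")

    Xtr = train[feature_cols].to_numpy(dtype=float)
    ytr = train["membership"].to_numpy(dtype=int)
    Xev = evl[feature_cols].to_numpy(dtype=float)
    yev = evl["membership"].to_numpy(dtype=int)

    scaler = StandardScaler().fit(Xtr)
    Xtr_s = scaler.transform(Xtr)
    Xev_s = scaler.transform(Xev)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf = LogisticRegression(penalty=None, max_iter=2000, random_state=seed)
        clf.fit(Xtr_s, ytr)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            clf = LogisticRegression(C=100.0, max_iter=5000, random_state=seed)
            clf.fit(Xtr_s, ytr)

    scores = clf.predict_proba(Xev_s)[:, 1]
    est = auroc(scores, yev)
    lo, hi = bootstrap_ci(auroc, scores, yev, n_boot=n_boot, seed=seed)
    return AttackResult(est, lo, hi, len(ytr), len(yev))


# ---------------------------------------------------------------------------
# Student-side audit
# ---------------------------------------------------------------------------


def logit_dispersion(model: MultiHeadModel, docs: Sequence[Document]) -> float:
    """Mean (over outcomes) standard deviation of the model's logits across
    a document set; near-zero dispersion is the constant-output collapse."""
    Z = model.predict_logits(docs).to_numpy()
    return float(Z.std(axis=0).mean())


def audit_student(
    teacher: MultiHeadModel,
    public_docs: Sequence[Document],
    member_docs: Sequence[Document],
    nonmember_docs: Sequence[Document],
    member_labels: pd.DataFrame,
    nonmember_labels: pd.DataFrame,
    doc_filter: Callable[[str], bool] = passes_discharge_filter,
    student_config: TrainConfig | None = None,
    train_frac: float = 0.6,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Repeat the attack against a student distilled from the overfit teacher.

    The student is trained only on public documents soft-labeled by the
    (overfit) teacher; the attack then uses student logits in place of
    teacher logits. Also reports the student's and teacher's logit dispersion
    over the audit documents — a low student/teacher ratio reproduces the
    constant-output collapse.
    """
    student_config = student_config or TrainConfig(
        learning_rate=0.05, epochs=60, weight_decay=1e-4,
        seed=seed, early_stop_metric="none",
    )
    overfit_logits = soft_label_public(teacher, public_docs, doc_filter)
    student = train_student(
        public_docs,
        overfit_logits,
        tune_docs=[],
        tune_labels=None,
        schema=teacher.schema,
        encoder_config=teacher.config,
        train_config=student_config,
    )
    records = build_attack_dataset(
        student, member_docs, nonmember_docs, member_labels, nonmember_labels,
        train_frac=train_frac, seed=seed,
    )
    result = run_attack(records, n_boot=n_boot, seed=seed)
    audit_docs = list(member_docs) + list(nonmember_docs)
    disp_student = logit_dispersion(student, audit_docs)
    disp_teacher = logit_dispersion(teacher, audit_docs)
    return {
        "student": student,
        "attack": result,
        "student_dispersion": disp_student,
        "teacher_dispersion": disp_teacher,
        "dispersion_ratio": disp_student / disp_teacher if disp_teacher > 0 else np.nan,
    }
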