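"""End-to-end experiment orchestration on synthetic corpora.

``run_distillation_experiment`` reproduces the full pipeline: generate a
private site-A corpus, split it at the patient level (80/10/10), train the
teacher, soft-label a filtered public corpus, train soft- and hard-label
students, and evaluate everything on the site-A test split and on external
site-B corpora that differ from site A only by a vocabulary shift. The
survival arm trains a risk teacher/student pair and reports c-indexes.

``run_privacy_experiment`` runs the membership-inference audit: overfit a
notes teacher on a small member sample, attack it, distill a student from
the overfit teacher through a public corpus, and attack the student.

Every stage draws its seed deterministically from the master seed; rerunning
with the same config yields byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .documents import (
    FILTERS,
    Document,
    split_cohort,
    write_corpus,
    write_table,
)
from .distillation import (
    TrainConfig,
    soft_label_public,
    train_student,
    train_student_hard,
    train_survival_student,
    train_survival_teacher,
    train_teacher,
)
from .encoder import EncoderConfig
from .evaluation import evaluate_model, evaluate_survival_model
from .privacy import (
    audit_student,
    build_attack_dataset,
    logit_dispersion,
    overfit_teacher,
    run_attack,
)
from .synthetic import GeneratorConfig, generate_labeled_corpus, generate_public_corpus
from scipy.special import expit

logger = logging.getLogger(__name__)


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministically fan a master seed out to per-stage seeds (< 2^31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


@dataclass
class AuditSettings:
    """Membership-inference audit configuration."""

    n_members: int = 100
    n_nonmembers: int = 100
    train_frac: float = 0.6
    overfit_max_epochs: int = 4000
    overfit_target_loss: float = 1e-3
    public_n_docs: int = 3000
    student_epochs: int = 60


@dataclass
class ExperimentConfig:
    """Full configuration for the distillation and privacy experiments.

    Site B shares the site-A generator except for ``site_shift`` — external
    validation differs from internal by vocabulary style alone.
    """

    site_a: GeneratorConfig = field(default_factory=GeneratorConfig)
    site_b_n_patients: int = 400
    site_b_shifts: tuple[float, ...] = (0.0, 0.5)
    public_n_docs: int = 5000
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    teacher_train: TrainConfig = field(
        default_factory=lambda: TrainConfig(learning_rate=0.5, epochs=40)
    )
    student_train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            learning_rate=0.05, epochs=60, early_stop_metric="tune_auroc"
        )
    )
    survival_train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            learning_rate=0.003, epochs=200, early_stop_metric="none"
        )
    )
    survival_student_train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            learning_rate=0.005, epochs=80, early_stop_metric="none"
        )
    )
    audit: AuditSettings = field(default_factory=AuditSettings)
    # Long-form notes carry a far weaker, noisier lexical signal than
    # imaging reports, so the audit corpus uses low cue fidelity and a
    # weak context channel; this is the regime in which an overfit teacher
    # must memorize rather than generalize.
    audit_generator: GeneratorConfig = field(
        default_factory=lambda: GeneratorConfig(
            schema_name="NOTE_3", n_patients=500, docs_per_patient=1,
            cue_fidelity=0.35, cue_noise=0.15, aux_rate_pos=0.5, aux_rate_neg=0.3,
            id_mentions=(30, 40),
        )
    )
    n_boot: int = 200
    level: float = 0.95
    master_seed: int = 0

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def default_experiment_config(seed: int = 0, schema_name: str = "IMAGING_10") -> ExperimentConfig:
    """The default desk-scale study conditions: 2000 private documents
    (1000 patients x 2), 5000 public documents, cue fidelity 0.9."""
    return ExperimentConfig(
        site_a=GeneratorConfig(schema_name=schema_name, n_patients=1000, docs_per_patient=2),
        master_seed=seed,
    )


class StageFailure(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str, fn: Callable, *args, **kwargs):
    t0 = _time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        logger.error("stage %s: failed (%s)", name, exc)
        raise StageFailure(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done in %.2fs", name, _time.perf_counter() - t0)
    return result


def _maybe_save(outdir: Path | None, name: str, obj) -> None:
    if outdir is None:
        return
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    if name.endswith(".jsonl"):
        write_corpus(obj, path)
    elif name.endswith(".csv"):
        if obj.index.name == "doc_id":
            write_table(obj, path)
        else:
            obj.to_csv(path, index=False)
    elif name.endswith(".json"):
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
    elif name.endswith(".npz"):
        obj.save(path)


def _metric_summary(frame: pd.DataFrame, metric: str = "auroc") -> dict[str, float]:
    sub = frame[(frame["metric"] == metric) & (frame["subgroup"].isna())]
    return {row["outcome"]: float(row["estimate"]) for _, row in sub.iterrows()}


def run_distillation_experiment(
    config: ExperimentConfig, outdir: str | Path | None = None
) -> dict:
    """Run the full classification + survival distillation experiment.

    Returns a report dict with teacher metrics on the site-A test split,
    student metrics on site-A and on each site-B variant, the soft- vs
    hard-label student comparison, and the survival-arm c-indexes. When
    ``outdir`` is given, corpora, models and tidy metric CSVs are persisted
    there; completed artifacts survive a failing stage.
    """
    outdir = Path(outdir) if outdir is not None else None
    seeds = child_seeds(config.master_seed, 12)
    schema = config.site_a.schema
    filter_mode = "imaging" if schema.name == "IMAGING_10" else "discharge"
    doc_filter = FILTERS[filter_mode]

    if outdir is not None:
        _maybe_save(outdir, "config.json", config.to_dict())

    # -- corpora -----------------------------------------------------------
    cfg_a = dataclasses.replace(config.site_a, seed=seeds[0], site="siteA")
    corpus_a = _stage("generate_site_a", generate_labeled_corpus, cfg_a)
    split = _stage(
        "split_cohort",
        split_cohort,
        sorted({d.patient_id for d in corpus_a.documents}),
        seed=seeds[1],
    )
    train_docs = split.documents(corpus_a.documents, "train")
    tune_docs = split.documents(corpus_a.documents, "tune")
    test_docs = split.documents(corpus_a.documents, "test")

    site_b: dict[float, object] = {}
    for i, shift in enumerate(config.site_b_shifts):
        cfg_b = dataclasses.replace(
            config.site_a,
            n_patients=config.site_b_n_patients,
            site="siteB",
            site_shift=shift,
            seed=seeds[2] + i,
        )
        site_b[shift] = _stage(f"generate_site_b_shift{shift}", generate_labeled_corpus, cfg_b)

    cfg_pub = dataclasses.replace(config.site_a, seed=seeds[3])
    public_docs = _stage(
        "generate_public", generate_public_corpus, cfg_pub, config.public_n_docs
    )
    if outdir is not None:
        corpus_a.save(outdir / "site_a")
        _maybe_save(outdir, "public_corpus.jsonl", public_docs)

    # -- teacher -----------------------------------------------------------
    teacher = _stage(
        "train_teacher",
        train_teacher,
        train_docs,
        corpus_a.labels,
        tune_docs,
        corpus_a.labels,
        schema,
        config.encoder,
        dataclasses.replace(config.teacher_train, seed=seeds[4]),
    )
    _maybe_save(outdir, "teacher.npz", teacher)

    ev_kwargs = dict(n_boot=config.n_boot, level=config.level)
    teacher_metrics = _stage(
        "evaluate_teacher", evaluate_model, teacher, test_docs, corpus_a.labels,
        schema, None, seed=seeds[5], **ev_kwargs,
    )
    _maybe_save(outdir, "metrics_teacher_siteA.csv", teacher_metrics)

    # -- soft-label public + students -------------------------------------
    teacher_logits = _stage("soft_label_public", soft_label_public, teacher, public_docs, doc_filter)
    _maybe_save(outdir, "public_teacher_logits.csv", teacher_logits)

    student = _stage(
        "train_student",
        train_student,
        public_docs,
        teacher_logits,
        tune_docs,
        corpus_a.labels,
        schema,
        config.encoder,
        dataclasses.replace(config.student_train, seed=seeds[6]),
    )
    _maybe_save(outdir, "student.npz", student)

    hard_labels = (expit(teacher_logits) > 0.5).astype(int)
    hard_student = _stage(
        "train_student_hard",
        train_student_hard,
        public_docs,
        hard_labels,
        schema,
        tune_docs,
        corpus_a.labels,
        config.encoder,
        dataclasses.replace(config.student_train, learning_rate=0.5, seed=seeds[7]),
    )

    student_metrics_a = _stage(
        "evaluate_student_siteA", evaluate_model, student, test_docs, corpus_a.labels,
        schema, None, seed=seeds[5], **ev_kwargs,
    )
    hard_metrics_a = _stage(
        "evaluate_hard_student_siteA", evaluate_model, hard_student, test_docs,
        corpus_a.labels, schema, None, seed=seeds[5], **ev_kwargs,
    )
    student_metrics_b = {}
    teacher_metrics_b = {}
    for shift, corpus_b in site_b.items():
        student_metrics_b[shift] = _stage(
            f"evaluate_student_siteB_shift{shift}",
            evaluate_model, student, corpus_b.documents, corpus_b.labels,
            schema, None, seed=seeds[5], **ev_kwargs,
        )
        teacher_metrics_b[shift] = _stage(
            f"evaluate_teacher_siteB_shift{shift}",
            evaluate_model, teacher, corpus_b.documents, corpus_b.labels,
            schema, None, seed=seeds[5], **ev_kwargs,
        )
    if outdir is not None:
        _maybe_save(outdir, "metrics_student_siteA.csv", student_metrics_a)
        _maybe_save(outdir, "metrics_hard_student_siteA.csv", hard_metrics_a)
        for shift, frame in student_metrics_b.items():
            _maybe_save(outdir, f"metrics_student_siteB_shift{shift}.csv", frame)

    # -- survival arm ------------------------------------------------------
    survival_teacher = _stage(
        "train_survival_teacher",
        train_survival_teacher,
        train_docs,
        corpus_a.survival,
        config.encoder,
        dataclasses.replace(config.survival_train, seed=seeds[8]),
    )
    teacher_cindex = _stage(
        "evaluate_survival_teacher", evaluate_survival_model, survival_teacher,
        test_docs, corpus_a.survival, seed=seeds[9], **ev_kwargs,
    )
    risk_scores = _stage(
        "risk_label_public", soft_label_public, survival_teacher, public_docs, doc_filter
    )
    survival_student = _stage(
        "train_survival_student",
        train_survival_student,
        public_docs,
        risk_scores,
        config.encoder,
        dataclasses.replace(config.survival_student_train, seed=seeds[10]),
    )
    student_cindex = _stage(
        "evaluate_survival_student", evaluate_survival_model, survival_student,
        test_docs, corpus_a.survival, seed=seeds[9], **ev_kwargs,
    )
    survival_b = {}
    for shift, corpus_b in site_b.items():
        survival_b[shift] = _stage(
            f"evaluate_survival_student_siteB_shift{shift}",
            evaluate_survival_model, survival_student, corpus_b.documents,
            corpus_b.survival, seed=seeds[9], **ev_kwargs,
        )
    _maybe_save(outdir, "survival_teacher.npz", survival_teacher)
    _maybe_save(outdir, "survival_student.npz", survival_student)

    report = {
        "config": config.to_dict(),
        "n_documents": {
            "site_a_train": len(train_docs),
            "site_a_tune": len(tune_docs),
            "site_a_test": len(test_docs),
            "public": len(public_docs),
            "public_labeled": len(teacher_logits),
            **{f"site_b_shift{s}": len(c.documents) for s, c in site_b.items()},
        },
        "teacher_auroc": _metric_summary(teacher_metrics),
        "student_auroc_site_a": _metric_summary(student_metrics_a),
        "hard_student_auroc_site_a": _metric_summary(hard_metrics_a),
        "student_auroc_site_b": {
            str(s): _metric_summary(f) for s, f in student_metrics_b.items()
        },
        "teacher_auroc_site_b": {
            str(s): _metric_summary(f) for s, f in teacher_metrics_b.items()
        },
        "survival": {
            "teacher_cindex": teacher_cindex.estimate,
            "teacher_cindex_ci": [teacher_cindex.ci_low, teacher_cindex.ci_high],
            "student_cindex": student_cindex.estimate,
            "student_cindex_ci": [student_cindex.ci_low, student_cindex.ci_high],
            "student_cindex_site_b": {str(s): r.estimate for s, r in survival_b.items()},
        },
        "metrics": {
            "teacher_site_a": teacher_metrics,
            "student_site_a": student_metrics_a,
            "hard_student_site_a": hard_metrics_a,
            "student_site_b": student_metrics_b,
            "teacher_site_b": teacher_metrics_b,
        },
        "models": {
            "teacher": teacher,
            "student": student,
            "hard_student": hard_student,
            "survival_teacher": survival_teacher,
            "survival_student": survival_student,
        },
    }
    if outdir is not None:
        serializable = {
            k: v for k, v in report.items() if k not in ("metrics", "models")
        }
        _maybe_save(outdir, "report.json", serializable)
    return report


def run_privacy_experiment(
    config: ExperimentConfig, outdir: str | Path | None = None
) -> dict:
    """Run the membership-inference audit end to end.

    Overfits a notes teacher on ``n_members`` private notes, attacks it with
    patient-disjoint nonmembers, distills a student from the overfit teacher
    through a public discharge-summary corpus, attacks the student the same
    way, and reports both attack AUROCs plus the logit-dispersion ratio.
    """
    outdir = Path(outdir) if outdir is not None else None
    seeds = child_seeds(config.master_seed ^ 0x5EED, 8)
    a = config.audit
    gen = dataclasses.replace(config.audit_generator, seed=seeds[0])
    corpus = _stage("generate_audit_corpus", generate_labeled_corpus, gen)
    warnings_list: list[str] = []

    docs_by_patient: dict[str, list[Document]] = {}
    for d in corpus.documents:
        docs_by_patient.setdefault(d.patient_id, []).append(d)
    patients = sorted(docs_by_patient)
    need = a.n_members + a.n_nonmembers
    if len(patients) < need:
        raise StageFailure(
            f"audit needs {need} patients, corpus has {len(patients)}"
        )
    rng = np.random.default_rng(seeds[1])
    picked = [patients[i] for i in rng.permutation(len(patients))[:need]]
    member_docs = [docs_by_patient[p][0] for p in picked[: a.n_members]]
    nonmember_docs = [docs_by_patient[p][0] for p in picked[a.n_members :]]
    if a.n_members < 30:
        warnings_list.append(
            f"unstable estimate: only {a.n_members} member documents"
        )

    teacher = _stage(
        "overfit_teacher",
        overfit_teacher,
        member_docs,
        corpus.labels,
        corpus.schema,
        config.encoder,
        max_epochs=a.overfit_max_epochs,
        target_loss=a.overfit_target_loss,
        seed=seeds[2],
    )

    def _attack(model, seed):
        records = build_attack_dataset(
            model, member_docs, nonmember_docs, corpus.labels, corpus.labels,
            train_frac=a.train_frac, seed=seed,
        )
        return run_attack(records, n_boot=max(config.n_boot, 100), seed=seed)

    try:
        teacher_attack = _stage("teacher_attack", _attack, teacher, seeds[3])
    except StageFailure as exc:
        teacher_attack = None
        warnings_list.append(f"teacher attack undefined: {exc}")

    cfg_pub = dataclasses.replace(gen, seed=seeds[4])
    public_docs = _stage(
        "generate_audit_public", generate_public_corpus, cfg_pub, a.public_n_docs
    )
    try:
        student_part = _stage(
            "audit_student",
            audit_student,
            teacher,
            public_docs,
            member_docs,
            nonmember_docs,
            corpus.labels,
            corpus.labels,
            student_config=TrainConfig(
                learning_rate=0.05, epochs=a.student_epochs, weight_decay=1e-4,
                seed=seeds[5], early_stop_metric="none",
            ),
            train_frac=a.train_frac,
            n_boot=max(config.n_boot, 100),
            seed=seeds[6],
        )
    except StageFailure as exc:
        warnings_list.append(f"student attack undefined: {exc}")
        student_part = {
            "attack": None,
            "student_dispersion": float("nan"),
            "dispersion_ratio": float("nan"),
        }

    audit_docs = member_docs + nonmember_docs
    report = {
        "n_members": a.n_members,
        "n_nonmembers": a.n_nonmembers,
        "overfit_evidence": teacher.meta["overfit"],
        "teacher_attack": (
            None
            if teacher_attack is None
            else {
                "auroc": teacher_attack.auroc,
                "ci": [teacher_attack.ci_low, teacher_attack.ci_high],
                "n_train": teacher_attack.n_train,
                "n_eval": teacher_attack.n_eval,
            }
        ),
        "student_attack": (
            None
            if student_part["attack"] is None
            else {
                "auroc": student_part["attack"].auroc,
                "ci": [student_part["attack"].ci_low, student_part["attack"].ci_high],
            }
        ),
        "teacher_dispersion": logit_dispersion(teacher, audit_docs),
        "student_dispersion": student_part["student_dispersion"],
        "dispersion_ratio": student_part["dispersion_ratio"],
        "warnings": warnings_list,
    }
    _maybe_save(outdir, "audit.json", report)
    return report
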