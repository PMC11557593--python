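"""Losses, teacher/student training, soft labeling, the privacy contract,
and the survival arm."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import oncodistill as od
from oncodistill.distillation import (
    CohortOverlapError,
    PrivacyContractError,
    TrainConfig,
    bce_multilabel_loss,
    mse_distill_loss,
    soft_label_public,
    survival_nll,
    train_student,
    train_student_hard,
    train_survival_student,
    train_survival_teacher,
    train_teacher,
)
from oncodistill.documents import passes_discharge_filter
from oncodistill.encoder import EncoderConfig
from oncodistill.evaluation import auroc


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def test_bce_hand_values():
    assert bce_multilabel_loss([[0.0]], [[1.0]]) == pytest.approx(math.log(2), abs=1e-12)
    assert bce_multilabel_loss([[50.0]], [[1.0]]) < 1e-9
    expected = 2 * math.log(1 + math.exp(-1))
    assert bce_multilabel_loss([[1.0, -1.0]], [[1.0, 0.0]]) == pytest.approx(expected, abs=1e-12)


def test_bce_rejects_nonbinary_labels_and_shape_mismatch():
    with pytest.raises(ValueError):
        bce_multilabel_loss([[0.0]], [[0.5]])
    with pytest.raises(ValueError):
        bce_multilabel_loss([[0.0, 1.0]], [[1.0]])


def test_mse_hand_values_and_translation_invariance():
    assert mse_distill_loss([[1.0, 2.0]], [[1.0, 2.0]]) == 0.0
    assert mse_distill_loss([[0.0, 2.0]], [[1.0, 0.0]]) == pytest.approx(2.5)
    a, b = np.array([[0.3, -1.2]]), np.array([[1.1, 0.4]])
    assert mse_distill_loss(a + 7.0, b + 7.0) == pytest.approx(mse_distill_loss(a, b))
    with pytest.raises(ValueError):
        mse_distill_loss([[1.0]], [[1.0, 2.0]])


def test_survival_nll_hand_values():
    assert survival_nll([0.0], [1.0], [1]) == pytest.approx(1.0, abs=1e-12)
    assert survival_nll([0.0], [2.0], [0]) == pytest.approx(2.0, abs=1e-12)
    assert survival_nll([math.log(2)], [1.0], [1]) == pytest.approx(2 - math.log(2), abs=1e-12)
    with pytest.raises(ValueError):
        survival_nll([0.0], [-1.0], [1])
    with pytest.raises(ValueError):
        survival_nll([0.0], [1.0], [2])


def test_survival_nll_grid_minimum_matches_closed_form():
    # one observed event at time t: argmin_eta exp(eta) t - eta = -ln t,
    # minimum value 1 + ln t
    t = 1.7
    grid = np.arange(-5, 5, 1e-3)
    vals = [survival_nll([eta], [t], [1]) for eta in grid]
    k = int(np.argmin(vals))
    assert grid[k] == pytest.approx(-math.log(t), abs=2e-3)
    assert vals[k] == pytest.approx(1 + math.log(t), abs=1e-5)


def test_losses_nonnegative_on_generated_data():
    rng = np.random.default_rng(0)
    z = rng.normal(size=(20, 3))
    y = rng.integers(0, 2, size=(20, 3)).astype(float)
    assert bce_multilabel_loss(z, y) >= 0
    assert mse_distill_loss(z, z + rng.normal(size=z.shape)) >= 0


# ---------------------------------------------------------------------------
# Teacher training
# ---------------------------------------------------------------------------

FAST = TrainConfig(learning_rate=0.5, epochs=15, seed=0)
ENC = EncoderConfig(n_features=4096)


def _split_docs(corpus, split):
    return (
        split.documents(corpus.documents, "train"),
        split.documents(corpus.documents, "tune"),
        split.documents(corpus.documents, "test"),
    )


def test_teacher_separable_corpus_perfect_training_auroc():
    cfg = od.GeneratorConfig(schema_name="NOTE_3", n_patients=150, docs_per_patient=1,
                             cue_fidelity=1.0, cue_noise=0.0, seed=21)
    corpus = od.generate_labeled_corpus(cfg)
    split = od.split_cohort(sorted({d.patient_id for d in corpus.documents}), seed=1)
    tr, tu, _ = _split_docs(corpus, split)
    model = train_teacher(tr, corpus.labels, tu, corpus.labels, corpus.schema, ENC,
                          TrainConfig(learning_rate=0.5, epochs=30, seed=0))
    logits = model.predict_logits(tr)
    y = corpus.labels.loc[logits.index]
    for o in corpus.schema.outcomes:
        if 0 < y[o].sum() < len(y):
            assert auroc(logits[o], y[o]) == 1.0


def test_teacher_training_is_deterministic(small_note_corpus, small_split):
    tr, tu, _ = _split_docs(small_note_corpus, small_split)
    lab = small_note_corpus.labels
    a = train_teacher(tr, lab, tu, lab, small_note_corpus.schema, ENC, FAST)
    b = train_teacher(tr, lab, tu, lab, small_note_corpus.schema, ENC, FAST)
    assert np.array_equal(a.weights, b.weights) and np.array_equal(a.bias, b.bias)


def test_teacher_all_negative_outcome_trains_and_pushes_logits_down():
    cfg = od.GeneratorConfig(schema_name="NOTE_3", n_patients=150, docs_per_patient=1,
                             prevalence={"response": 0.0}, seed=5)
    corpus = od.generate_labeled_corpus(cfg)
    split = od.split_cohort(sorted({d.patient_id for d in corpus.documents}), seed=2)
    tr, tu, _ = _split_docs(corpus, split)
    model = train_teacher(tr, corpus.labels, tu, corpus.labels, corpus.schema, ENC,
                          TrainConfig(learning_rate=0.5, epochs=25, seed=0))
    assert model.predict_logits(tr)["response"].mean() < -1.0


def test_teacher_rejects_patient_overlap(small_note_corpus, small_split):
    tr, tu, _ = _split_docs(small_note_corpus, small_split)
    lab = small_note_corpus.labels
    with pytest.raises(CohortOverlapError):
        train_teacher(tr, lab, tr[:5], lab, small_note_corpus.schema, ENC, FAST)


# ---------------------------------------------------------------------------
# Soft labeling and the privacy contract
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def note_teacher(small_note_corpus, small_split):
    tr, tu, _ = _split_docs(small_note_corpus, small_split)
    lab = small_note_corpus.labels
    return train_teacher(tr, lab, tu, lab, small_note_corpus.schema, ENC,
                         TrainConfig(learning_rate=0.5, epochs=25, seed=3))


def test_soft_label_count_matches_independent_filter_count(note_teacher):
    cfg = od.GeneratorConfig(schema_name="NOTE_3", filter_trigger_rate=0.5, seed=9)
    pub = od.generate_public_corpus(cfg, 400)
    expected = sum(passes_discharge_filter(d.text) for d in pub)
    logits = soft_label_public(note_teacher, pub, passes_discharge_filter)
    assert len(logits) == expected
    assert np.isfinite(logits.to_numpy()).all()


def test_soft_label_empty_when_nothing_passes(note_teacher):
    cfg = od.GeneratorConfig(schema_name="NOTE_3", filter_trigger_rate=0.0, seed=9)
    pub = od.generate_public_corpus(cfg, 60)
    assert len(soft_label_public(note_teacher, pub, passes_discharge_filter)) == 0


def test_student_rejects_private_documents(note_teacher, small_note_corpus):
    private_docs = small_note_corpus.documents[:30]
    logits = note_teacher.predict_logits(private_docs)
    with pytest.raises(PrivacyContractError):
        train_student(private_docs, logits, [], None, small_note_corpus.schema, ENC, FAST)


def test_student_rejects_empty_public_corpus(note_teacher, small_note_corpus):
    empty = pd.DataFrame(columns=list(small_note_corpus.schema.outcomes),
                         index=pd.Index([], name="doc_id"))
    with pytest.raises(ValueError):
        train_student([], empty, [], None, small_note_corpus.schema, ENC, FAST)


def test_student_on_zero_teacher_converges_to_near_zero_logits(small_note_corpus):
    cfg = od.GeneratorConfig(schema_name="NOTE_3", filter_trigger_rate=1.0, seed=8)
    pub = od.generate_public_corpus(cfg, 300)
    zero_teacher = od.MultiHeadModel.zeros(ENC, small_note_corpus.schema)
    targets = soft_label_public(zero_teacher, pub, passes_discharge_filter)
    student = train_student(pub, targets, [], None, small_note_corpus.schema, ENC,
                            TrainConfig(learning_rate=0.05, epochs=20, seed=0,
                                        early_stop_metric="none"))
    out = student.predict_logits(pub).to_numpy()
    assert np.abs(out).max() < 0.05
    assert student.meta["loss_trace"][-1] < 1e-4


def test_student_records_public_provenance_and_fresh_hash(note_teacher, small_note_corpus):
    cfg = od.GeneratorConfig(schema_name="NOTE_3", filter_trigger_rate=1.0, seed=8)
    pub = od.generate_public_corpus(cfg, 200)
    targets = soft_label_public(note_teacher, pub, passes_discharge_filter)
    student = train_student(pub, targets, [], None, small_note_corpus.schema, ENC,
                            TrainConfig(learning_rate=0.05, epochs=10, seed=0,
                                        early_stop_metric="none"))
    assert student.meta["training_provenance"] == "public"
    assert student.config.hash_seed != note_teacher.config.hash_seed


# ---------------------------------------------------------------------------
# Hard-label student
# ---------------------------------------------------------------------------


def _note_world(seed, n_private=800, n_public=2000):
    cfg = od.GeneratorConfig(schema_name="NOTE_3", n_patients=n_private,
                             docs_per_patient=1, filter_trigger_rate=1.0, seed=seed)
    corpus = od.generate_labeled_corpus(cfg)
    split = od.split_cohort(sorted({d.patient_id for d in corpus.documents}), seed=seed)
    pub = od.generate_public_corpus(dataclasses.replace(cfg, seed=seed + 100), n_public)
    return corpus, split, pub


def test_hard_student_on_thresholded_teacher_labels_ranks_like_soft_student():
    corpus, split, pub = _note_world(33)
    tr, tu, te = _split_docs(corpus, split)
    lab = corpus.labels
    teacher = train_teacher(tr, lab, tu, lab, corpus.schema, ENC,
                            TrainConfig(learning_rate=0.5, epochs=30, seed=1))
    targets = soft_label_public(teacher, pub, passes_discharge_filter)
    soft = train_student(pub, targets, tu, lab, corpus.schema, ENC,
                         TrainConfig(learning_rate=0.05, epochs=40, seed=1,
                                     early_stop_metric="tune_auroc"))
    hard_labels = (targets > 0).astype(int)
    hard = train_student_hard(pub, hard_labels, corpus.schema, tu, lab, ENC,
                              TrainConfig(learning_rate=0.5, epochs=40, seed=1,
                                          early_stop_metric="tune_auroc"))
    zs = soft.predict_logits(te)
    zh = hard.predict_logits(te)
    rhos = [spearmanr(zs[o], zh[o]).statistic for o in corpus.schema.outcomes]
    assert np.mean(rhos) >= 0.8


def test_hard_student_on_coin_flip_labels_is_uninformative():
    corpus, split, pub = _note_world(44, n_private=400, n_public=1500)
    _, _, te = _split_docs(corpus, split)
    rng = np.random.default_rng(0)
    random_labels = pd.DataFrame(
        rng.integers(0, 2, size=(len(pub), 3)),
        index=pd.Index([d.doc_id for d in pub], name="doc_id"),
        columns=list(corpus.schema.outcomes),
    )
    hard = train_student_hard(pub, random_labels, corpus.schema, (), None, ENC,
                              TrainConfig(learning_rate=0.5, epochs=25, seed=2,
                                          early_stop_metric="none"))
    logits = hard.predict_logits(te)
    y = corpus.labels.loc[logits.index]
    aurocs = [auroc(logits[o], y[o]) for o in corpus.schema.outcomes
              if 0 < y[o].sum() < len(y)]
    assert abs(np.mean(aurocs) - 0.5) < 0.05


def test_hard_student_rejects_nonbinary_labels():
    corpus, _, pub = _note_world(55, n_private=30, n_public=50)
    bad = pd.DataFrame(0.5, index=pd.Index([d.doc_id for d in pub], name="doc_id"),
                       columns=list(corpus.schema.outcomes))
    with pytest.raises(ValueError):
        train_student_hard(pub, bad, corpus.schema, (), None, ENC, FAST)


def test_all_positive_labels_yield_constant_high_logits():
    corpus, _, pub = _note_world(66, n_private=30, n_public=400)
    ones = pd.DataFrame(1, index=pd.Index([d.doc_id for d in pub], name="doc_id"),
                        columns=list(corpus.schema.outcomes))
    hard = train_student_hard(pub, ones, corpus.schema, (), None, ENC,
                              TrainConfig(learning_rate=0.5, epochs=30, seed=0,
                                          early_stop_metric="none"))
    out = hard.predict_logits(pub).to_numpy()
    assert out.min() > 1.0  # uniformly confident positive


# ---------------------------------------------------------------------------
# Distillation fidelity grows with public corpus size
# ---------------------------------------------------------------------------


def test_teacher_student_gap_shrinks_with_public_corpus_size():
    gaps = {1500: [], 6000: []}
    for seed in range(5):
        corpus, split, _ = _note_world(seed, n_private=700)
        tr, tu, te = _split_docs(corpus, split)
        lab = corpus.labels
        teacher = train_teacher(tr, lab, tu, lab, corpus.schema, ENC,
                                TrainConfig(learning_rate=0.5, epochs=25, seed=seed))
        zt = teacher.predict_logits(te)
        y = lab.loc[zt.index]
        outcomes = [o for o in corpus.schema.outcomes if 0 < y[o].sum() < len(y)]
        at = {o: auroc(zt[o], y[o]) for o in outcomes}
        cfg_pub = od.GeneratorConfig(schema_name="NOTE_3", filter_trigger_rate=1.0,
                                     seed=seed + 900)
        big_pub = od.generate_public_corpus(cfg_pub, 6000)
        for n in gaps:
            pub = big_pub[:n]
            targets = soft_label_public(teacher, pub, passes_discharge_filter)
            student = train_student(pub, targets, tu, lab, corpus.schema, ENC,
                                    TrainConfig(learning_rate=0.05, epochs=30,
                                                seed=seed, early_stop_metric="tune_auroc"))
            zs = student.predict_logits(te)
            gaps[n].append(np.mean([abs(at[o] - auroc(zs[o], y[o])) for o in outcomes]))
    assert np.mean(gaps[6000]) <= np.mean(gaps[1500]) + 0.01


# ---------------------------------------------------------------------------
# Survival arm
# ---------------------------------------------------------------------------


def test_survival_teacher_no_signal_when_hazard_flat():
    coefs = {o: 0.0 for o in od.IMAGING_10.outcomes}
    cfg = od.GeneratorConfig(n_patients=600, docs_per_patient=1, hazard_coefs=coefs,
                             seed=17)
    corpus = od.generate_labeled_corpus(cfg)
    split = od.split_cohort(sorted({d.patient_id for d in corpus.documents}), seed=1)
    tr, _, te = _split_docs(corpus, split)
    model = train_survival_teacher(tr, corpus.survival, ENC,
                                   TrainConfig(learning_rate=0.003, epochs=80,
                                               early_stop_metric="none"))
    from oncodistill.evaluation import c_index

    risks = model.predict_logits(te).iloc[:, 0]
    sub = corpus.survival.loc[risks.index]
    assert abs(c_index(risks, sub["time"], sub["event"]) - 0.5) < 0.07


def test_survival_student_on_constant_scores_outputs_constant():
    cfg = od.GeneratorConfig(filter_trigger_rate=1.0, seed=19)
    pub = od.generate_public_corpus(cfg, 300)
    const = pd.DataFrame({"mortality_risk": -1.5},
                         index=pd.Index([d.doc_id for d in pub], name="doc_id"))
    student = train_survival_student(pub, const, ENC,
                                     TrainConfig(learning_rate=0.005, epochs=150,
                                                 early_stop_metric="none"))
    out = student.predict_logits(pub).to_numpy().ravel()
    assert out.std() < 0.1  # dispersion collapses toward the constant target
    assert abs(out.mean() + 1.5) < 0.1


def test_survival_student_rejects_private_documents(small_note_corpus):
    docs = small_note_corpus.documents[:10]
    tbl = pd.DataFrame({"mortality_risk": 0.0},
                       index=pd.Index([d.doc_id for d in docs], name="doc_id"))
    with pytest.raises(PrivacyContractError):
        train_survival_student(docs, tbl, ENC, FAST)
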