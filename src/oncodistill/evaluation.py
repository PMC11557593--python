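"""Per-document evaluation metrics: AUROC, AUPRC, best F1, null values,
percentile bootstrap confidence intervals, subgroup stratification, and
Harrell's c-index for the survival arm.

Null values give each metric its no-skill reference: AUROC 0.5, AUPRC the
outcome prevalence p, and best F1 the always-guess-positive value
``2p / (p + 1)``.

AUROC and AUPRC (average precision with ties grouped as one step) are
computed via scikit-learn; the c-index via lifelines; best F1 by direct
threshold enumeration, with the threshold chosen in-sample on the evaluation
set — an optimistic metric by construction, reported as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from sklearn.metrics import average_precision_score, roc_auc_score

from .documents import Document, LabelSchema

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined on the given sample (e.g. a single
    label class, or no comparable survival pairs)."""


# ---------------------------------------------------------------------------
# Point metrics
# ---------------------------------------------------------------------------


def _check_binary(labels: np.ndarray) -> None:
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")


def auroc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative,
    ties credited 0.5 (the Mann-Whitney statistic)."""
    y = np.asarray(labels, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    _check_binary(y)
    if y.sum() in (0, len(y)):
        raise UndefinedMetricError("AUROC needs both a positive and a negative")
    return float(roc_auc_score(y, s))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve by average precision
    (step interpolation; tied scores grouped as one step)."""
    y = np.asarray(labels, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    _check_binary(y)
    if y.sum() == 0:
        raise UndefinedMetricError("AUPRC needs at least one positive")
    return float(average_precision_score(y, s))


def best_f1(scores, labels) -> float:
    """Maximum F1 over all score thresholds, predicting positive at
    ``score >= threshold``; candidate thresholds are the unique scores
    (the lowest of which predicts all-positive)."""
    y = np.asarray(labels, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    _check_binary(y)
    n_pos = y.sum()
    if n_pos == 0:
        raise UndefinedMetricError("best F1 needs at least one positive")

    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1.0 - y_sorted)
    # threshold candidates: last index of each tied-score block
    last_of_block = np.nonzero(np.diff(s_sorted, append=np.nan))[0]
    f1 = 2 * tp[last_of_block] / (2 * tp[last_of_block] + fp[last_of_block] + (n_pos - tp[last_of_block]))
    return float(f1.max())


def null_metrics(prevalence: float) -> tuple[float, float, float]:
    """(AUROC, AUPRC, best-F1) null values at outcome prevalence p:
    (0.50, p, 2p/(p+1))."""
    p = float(prevalence)
    if not (0.0 < p <= 1.0):
        raise ValueError("prevalence must be in (0, 1]")
    return 0.50, p, 2.0 * p / (p + 1.0)


def c_index(risk_scores, times, events) -> float:
    """Harrell's concordance index over comparable pairs (t_i < t_j with
    d_i = 1): the fraction where the earlier event carries the higher risk,
    risk ties credited 0.5."""
    eta = np.asarray(risk_scores, dtype=float).ravel()
    t = np.asarray(times, dtype=float).ravel()
    d = np.asarray(events, dtype=float).ravel()
    _check_binary(d)
    try:
        # lifelines scores concordance of *survival-time* predictions, so
        # pass the negated risk.
        return float(concordance_index(t, -eta, d))
    except ZeroDivisionError:
        raise UndefinedMetricError("no comparable pairs for the c-index") from None


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals
# ---------------------------------------------------------------------------


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    scores,
    labels,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a per-document metric.

    Documents are the resampling unit. Resamples on which the metric is
    undefined (e.g. a single-class draw) are redrawn; the redraw count is
    logged. Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    metric_fn(s, y)  # raises if undefined on the full sample

    rng = np.random.default_rng(seed)
    n = len(s)
    values = np.empty(n_boot)
    got = 0
    redraws = 0
    max_attempts = 20 * n_boot
    attempts = 0
    while got < n_boot:
        attempts += 1
        if attempts > max_attempts:
            raise UndefinedMetricError("bootstrap resamples persistently undefined")
        idx = rng.integers(0, n, size=n)
        try:
            values[got] = metric_fn(s[idx], y[idx])
            got += 1
        except UndefinedMetricError:
            redraws += 1
    if redraws:
        logger.debug("bootstrap redrew %d undefined resamples", redraws)
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return float(low), float(high)


def bootstrap_ci_survival(
    risk_scores, times, events, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval for the c-index (documents resampled)."""
    eta = np.asarray(risk_scores, dtype=float).ravel()
    packed = np.column_stack([times, events])

    def fn(e, yy):  # yy rows: (time, event)
        return c_index(e, yy[:, 0], yy[:, 1])

    # reuse the generic machinery with a 2-column "label"
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    fn(eta, packed)
    rng = np.random.default_rng(seed)
    n = len(eta)
    values = np.empty(n_boot)
    got = 0
    attempts = 0
    while got < n_boot:
        attempts += 1
        if attempts > 20 * n_boot:
            raise UndefinedMetricError("bootstrap resamples persistently undefined")
        idx = rng.integers(0, n, size=n)
        try:
            values[got] = fn(eta[idx], packed[idx])
            got += 1
        except UndefinedMetricError:
            continue
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return float(low), float(high)


# ---------------------------------------------------------------------------
# Model-level evaluation
# ---------------------------------------------------------------------------

_METRIC_FNS: dict[str, Callable] = {"auroc": auroc, "auprc": auprc, "best_f1": best_f1}


@dataclass
class MetricReport:
    """One metric for one outcome, with CI, null value and context."""

    outcome: str
    metric: str  # auroc | auprc | best_f1 | c_index
    estimate: float
    ci_low: float
    ci_high: float
    null_value: float
    n_documents: int
    subgroup: str | None = None
    undefined: bool = False


def reports_to_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Tidy one-row-per-(outcome, metric, subgroup) table."""
    return pd.DataFrame([vars(r) for r in reports])


def _subgroup_of(doc: Document, key: str) -> str:
    if hasattr(doc, key):
        return str(getattr(doc, key))
    return str(doc.extra.get(key, "unknown"))


def evaluate_scores(
    logits: pd.DataFrame,
    labels: pd.DataFrame,
    outcomes: Sequence[str],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    subgroup: str | None = None,
) -> list[MetricReport]:
    """Evaluate a doc_id-indexed logit table against binary labels."""
    reports: list[MetricReport] = []
    ids = logits.index
    y_all = labels.loc[ids]
    for j, outcome in enumerate(outcomes):
        s = logits[outcome].to_numpy(dtype=float)
        y = y_all[outcome].to_numpy(dtype=float)
        n = len(y)
        p = y.mean() if n else 0.0
        nulls = dict(zip(("auroc", "auprc", "best_f1"), null_metrics(p) if 0 < p <= 1 else (0.5, np.nan, np.nan)))
        for metric, fn in _METRIC_FNS.items():
            try:
                est = fn(s, y)
                lo, hi = bootstrap_ci(fn, s, y, n_boot=n_boot, level=level, seed=seed + 7 * j)
                reports.append(
                    MetricReport(outcome, metric, est, lo, hi, nulls[metric], n, subgroup)
                )
            except UndefinedMetricError:
                reports.append(
                    MetricReport(
                        outcome, metric, np.nan, np.nan, np.nan, nulls[metric], n,
                        subgroup, undefined=True,
                    )
                )
    return reports


def evaluate_model(
    model,
    docs: Sequence[Document],
    labels: pd.DataFrame,
    schema: LabelSchema | None = None,
    subgroup_key: str | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-document evaluation of a classification model.

    Returns a tidy frame with one row per outcome x metric, overall and —
    when ``subgroup_key`` names a document attribute or extra field (e.g.
    ``cancer_type``) — per subgroup level. Outcomes that are single-class in
    a subgroup are flagged undefined rather than silently dropped.
    """
    schema = schema or model.schema
    logits = model.predict_logits(docs)
    outcomes = list(schema.outcomes)
    reports = evaluate_scores(logits, labels, outcomes, n_boot, level, seed)
    if subgroup_key is not None:
        groups: dict[str, list[Document]] = {}
        for d in docs:
            groups.setdefault(_subgroup_of(d, subgroup_key), []).append(d)
        for tag in sorted(groups):
            sub_ids = [d.doc_id for d in groups[tag]]
            reports.extend(
                evaluate_scores(
                    logits.loc[sub_ids], labels, outcomes, n_boot, level, seed, subgroup=tag
                )
            )
    return reports_to_frame(reports)


def evaluate_survival_model(
    model,
    docs: Sequence[Document],
    survival: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> MetricReport:
    """c-index of a survival risk model on a document set, with bootstrap CI."""
    risks = model.predict_logits(docs).iloc[:, 0].to_numpy()
    sub = survival.loc[[d.doc_id for d in docs]]
    t = sub["time"].to_numpy(dtype=float)
    d = sub["event"].to_numpy(dtype=float)
    est = c_index(risks, t, d)
    lo, hi = bootstrap_ci_survival(risks, t, d, n_boot=n_boot, level=level, seed=seed)
    return MetricReport("survival", "c_index", est, lo, hi, 0.5, len(t))
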