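# oncodistill

Teacher–student distillation of **shareable** clinical-text outcome-extraction
models, with the full evaluation-metric suite and a membership-inference
privacy audit — exercisable end to end on synthetic clinical-like corpora.

## The problem

Cancer outcomes (presence of cancer, progression, response to therapy,
metastatic sites) are recorded as free text in imaging reports and oncologist
notes. Models trained to extract these outcomes directly from protected
health information (PHI) can memorize their training documents, so they
cannot be shared across centers: a membership-inference attack (MIA) on such
a model can tell whether a given patient's note was in its training set.

The teacher–student remedy implemented here:

1. Train a **teacher** on private labeled documents (per-outcome binary
   cross entropy over a multi-head classifier).
2. Run the teacher over a *public*, de-identified corpus (restricted by
   string-matching inclusion filters to documents that address cancer),
   recording its predicted log odds (`logits`) per outcome.
3. Train a freshly initialized **student** of the same architecture on the
   public text only, matching the teacher's logits under a mean-squared-error
   loss: `L = mean_{docs,heads} (z_student − z_teacher)²`.

The student never touches PHI, so it is the shareable artifact. The same
recipe distills a survival model: the teacher minimizes an exponential
proportional-hazards negative log-likelihood accommodating right-censoring,
`mean_i [exp(η_i)·t_i − d_i·η_i]`, and the student regresses onto the
teacher's scalar risk scores.

Evaluation is per-document: AUROC, AUPRC (average precision), and best F1,
each against its null value (0.50, the outcome prevalence `p`, and
`2p/(p+1)` respectively), with 95% percentile-bootstrap confidence
intervals; Harrell's c-index for the survival arm. The privacy audit
overfits a teacher to 100 notes, attacks it with a logistic regression
reading (true labels ⊕ model logits) for 100 member and 100 patient-disjoint
nonmember notes (60/40 train/eval), then repeats the attack against a
student distilled from the overfit teacher.

Real corpora of this kind are protected, so the package ships a synthetic
generator that reproduces the statistical structure the pipeline needs:
gated multi-label outcomes, lexical cues with controllable fidelity,
patient-identifier tokens in private text only, a site-style vocabulary
shift for external validation, filter-trigger strings, and label-dependent
censored survival times. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from oncodistill import default_experiment_config, run_distillation_experiment

report = run_distillation_experiment(default_experiment_config(seed=1), "run1")
print({k: round(v, 3) for k, v in report["teacher_auroc"].items()})
print(round(report["survival"]["teacher_cindex"], 3),
      round(report["survival"]["student_cindex"], 3))
```

This generates a private "site A" corpus (1000 patients × 2 imaging
reports), trains the teacher, soft-labels a 5000-document public corpus,
trains the student, and evaluates both at site A and at an external
"site B". With seed 1 it prints teacher test-set AUROCs

```
{'any_cancer': 0.997, 'progression': 0.989, 'response': 0.996, 'brain': 0.997,
 'bone': 0.966, 'lung': 0.999, 'liver': 0.999, 'adrenal': 0.994,
 'nodes': 1.0, 'peritoneum': 0.999}
0.744 0.741
```

— every outcome is extracted with high discrimination, and the survival
student matches its teacher's c-index (0.744 vs 0.741) without ever seeing a
private document. The `run1/` directory holds the corpora (JSONL), label and
logit tables (CSV), model files (the student file contains only parameters,
no text), and tidy metric CSVs with bootstrap CIs and null values.

The same pipeline is available from a shell:

```bash
oncodistill run-all --seed 1 --outdir run1
oncodistill audit --seed 1 --outdir run1        # membership-inference audit
oncodistill filter --doc-type imaging --in public.jsonl --out kept.jsonl
```

The audit report contrasts the overfit teacher (attack AUROC well above
chance) with the distilled student (attack near 0.5, logit dispersion
collapsed to a fraction of the teacher's).

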