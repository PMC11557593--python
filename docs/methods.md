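# Methods

## Pipeline

Documents are tokenized by lowercasing, whitespace splitting, and stripping
flanking punctuation, then truncated per document type: imaging reports keep
their first 512 tokens, long-form notes and discharge summaries keep their
last 4096 (left truncation, since the assessment usually sits at the end of
a note). Public-corpus inclusion uses two string filters, applied
case-insensitively: imaging documents must contain a disease term ("cancer",
"restaging", or a token starting with "malignan") *and* a modality term (ct,
mr, pet, nm as delimiter-bounded tokens — a bare substring would match words
like "eject" — or "mammo"); discharge summaries need only a disease term.
Cohorts are split at the patient level into 80/10/10 train/tune/test blocks
by shuffling patients under a seed and cutting contiguous blocks sized by
largest-remainder rounding, so sizes are deterministic (10 patients →
8/1/1).

The default encoder is a hashed bag of word n-grams (orders 1–2, 8192
buckets, CRC32 with an explicit seed, a second salted hash providing the
feature sign) feeding a multi-head linear model, one logit per outcome. The
contract — text in, one finite log-odds per outcome out — is what the
pipeline needs; heavier encoders plug in behind the `external` backend hook.
Teachers minimize summed per-head binary cross entropy (numerically stable
softplus form) by mini-batch gradient descent with weight decay, keeping the
epoch with the best tuning-set loss. Students are freshly initialized —
same widths and n-gram orders but a fresh hash seed, the hashing-trick
analogue of fresh weight initialization — and minimize the mean squared
logit difference to the teacher on filtered public documents, with model
selection by mean tuning-set AUROC on the private validation split. The
hard-label variant trains with BCE on assigned binary labels. The fresh
hash seed is also load-bearing for privacy: with a shared featurizer, hash
collisions would let a student address the very buckets an overfit teacher
used to memorize private-only tokens through unrelated public n-grams.

The survival teacher has a single risk head minimizing the exponential
proportional-hazards negative log-likelihood `mean[exp(η)t − d·η]` (cumulative
hazard for everyone, log-hazard only for observed deaths). This closed form
is chosen over a Cox partial likelihood because it is batch-decomposable and
matches the generator's constant-hazard simulation; its intercept is
initialized at the constant-hazard MLE `log(Σd/Σt)` so early gradients are
well scaled. The NLL of a continuous density can be negative when event
times are much smaller than one time unit; with month-scale times it is
positive in practice. The survival student regresses onto teacher risk
scores with MSE.

## Synthetic corpus model

Each patient draws a latent outcome vector: any-cancer is a root Bernoulli
(default 0.60); progression, response and the seven metastatic-site labels
are Bernoullis conditional on any-cancer = 1 (defaults 0.08–0.40) and are
forced to 0 otherwise (gating). All of a patient's documents share the
patient's labels. Text is a bag of background tokens (invented words, fixed
vocabulary of 400) into which label-driven material is spliced as atomic
segments (so phrases are never split):

* **Cues.** Each outcome has two interchangeable multi-token phrasings.
  Each is emitted independently with probability `cue_fidelity` in a
  positive document and `cue_noise` in a negative one; a genuinely positive
  mention repeats 1–3 times, a spurious one appears once. Two variants plus
  repetition are needed for the text to carry a strong, *learnable* signal:
  a single binary cue at fidelity 0.9 / noise 0.05 caps the achievable
  AUROC near 0.93 regardless of the model.
* **Context tokens.** Each outcome also has a 12-word auxiliary vocabulary
  emitted as a Poisson burst (`aux_rate_pos`, default 3.5) in positives and
  a trickle (`aux_rate_neg`, 0.15) in negatives — the diffuse wording signal
  real reports carry beyond key phrases.
* **Identifiers.** Private documents embed a patient-unique token
  (`id_mentions` occurrences; default 2–4 for imaging, 30–40 in the
  PHI-dense notes used by the audit). Public documents have none — they are
  de-identified. This channel is what an overfit model memorizes.
* **Site style.** A site shift `s` substitutes a fraction `s` of the
  background and context vocabulary with synonym forms, and dictates the
  *second* cue variant in a local dialect with probability `s`; the primary
  phrasing is universal. This is what makes models transfer imperfectly to
  an external site while still transferring.
* **Public documents** draw latent labels per document (never returned),
  carry a filter-trigger phrase with probability `filter_trigger_rate`, and
  cannot otherwise pass the filters (the invented vocabulary avoids every
  filter substring), so the pass rate equals the trigger rate exactly.

Survival: each patient's event time is exponential with hazard
`λ0·exp(β·labels)` (λ0 = 0.02/month; β defaults: +1.5 any-cancer, +1.2
progression, −1.0 response, +0.4…+1.0 per metastatic site), censored at an
independent uniform(0, C) draw with C = 60 months. These defaults put the
label-driven c-index ceiling near 0.76.

What the generator does **not** emulate: clinical grammar and negation,
section structure, inter-outcome textual interactions, annotation noise,
temporal drift, and realistic public/private domain mismatch (the degree of
mismatch is a free knob, not calibrated to any real corpus pair). Passing
tests therefore demonstrate that the pipeline's machinery — training,
distillation, filtering, evaluation, auditing — behaves correctly under the
assumed statistical structure, not that any particular performance level
would be attained on real clinical text.

## Evaluation

AUROC is the Mann-Whitney statistic (ties 0.5); AUPRC is average precision
with tied scores grouped as one step (step interpolation, not trapezoidal,
avoiding optimistic linear interpolation); best F1 maximizes F1 over all
distinct-score thresholds with prediction at `score ≥ threshold` — the
threshold is chosen on the evaluation set itself, an optimistic metric by
construction, reported as the protocol defines it. Null values: 0.50,
prevalence `p`, and `2p/(p+1)` (the always-positive classifier). Confidence
intervals are percentile bootstrap (default 1000 resamples; 200 in the
orchestrated experiments) resampling documents — evaluation is per-document
throughout, and whether patients or documents should be the resampling unit
is ambiguous; documents match the per-document evaluation and are flagged
here. Undefined resamples (single-class draws) are redrawn and counted.
Subgroup stratification (e.g. by cancer type) reports undefined
outcome/metric cells explicitly rather than dropping them. Harrell's
c-index scores comparable pairs (`t_i < t_j`, `d_i = 1`), risk ties 0.5,
via lifelines.

Two known small-sample artifacts are handled explicitly: an outcome can be
single-class in a 200-document test split (reported as undefined; the
experiment additionally evaluates models on an 800-document unshifted
external corpus where every outcome is estimable), and a percentile
bootstrap interval at a perfectly-separated estimate of 1.0 has zero width —
where such intervals are compared, they are widened by a rule-of-three bound
(3/m, m = positive count).

## Privacy audit

The audit corpus is weak-signal, PHI-dense notes (cue fidelity 0.35, noise
0.15, context rates 0.5/0.3, 30–40 identifier mentions): long-form notes
carry far less transferable lexical signal than imaging reports, and this is
the regime in which a teacher overfit to 100 notes must memorize rather than
generalize. The overfit teacher trains full-batch, no weight decay, no early
stopping, until training loss < 1e-3 (evidence recorded in the model
metadata; a miss warns rather than errors). The attack is a plain logistic
regression on standardized features (true labels ⊕ model logits), trained
on a membership-stratified 60% of the 200 audit notes and scored by AUROC on
the other 40% (stratification avoids degenerate single-class splits at this
size). An unpenalized fit is attempted first with a small-ridge fallback,
since 120 points with 6 features can be separable. The student-side audit
distills a student from the overfit teacher through a public discharge
corpus and repeats the attack on the student's logits; it also reports the
mean per-outcome standard deviation of student logits over the 200 audit
documents relative to the teacher's — dispersion collapse is the observable
form of "the student could not be fit". The student's inability to leak is
structural: the memorized component of the teacher lives on identifier
features that never occur (and, given the fresh hash seed, cannot be
addressed) in public text.

One deviation from the expected phenomenology is documented in the test
suite: for a deterministic linear teacher, membership leakage saturates
within the first unregularized epochs (the attack standardizes features, so
even tiny label-aligned perturbations separate members) and then stays flat
rather than growing with further training; the audit therefore checks
chance-level leakage for the untrained model and strong, stable leakage at
every trained level.

## Numerical choices

* Gradient steps: teacher BCE lr 0.5 (40 epochs, batch 256, weight decay
  1e-4); student MSE lr 0.05 (divergence begins near 0.2; the MSE gradient
  is not bounded the way the BCE gradient is); survival teacher lr 0.003,
  200 epochs (the exponential NLL is step-sensitive; η is clipped at ±30
  inside exp for mid-training excursions); survival student lr 0.005
  (single-head MSE lacks the 1/K head-average damping).
* Model selection: best tuning-set loss for teachers, best mean tuning-set
  AUROC for students, none for survival models and deliberately-overfit
  models. A diverged state (non-finite logits) is never selected.
* Largest-remainder split rounding breaks ties toward the earlier split
  (train, then tune).
* All randomness flows from explicit integer seeds; the experiment master
  seed fans out to stage seeds via a seed sequence, and identical
  configuration + seed reproduces byte-identical artifacts.
* Experiment scale (1000 × 2 private documents, 5000 public, 400 × 2 per
  external-site variant, 200 bootstrap resamples in orchestrated runs,
  medians over 3 experiment seeds and 5 audit seeds) was chosen as the
  package's desk-scale default study conditions.

## Known limitations

* The default encoder is linear over hashed n-grams; findings about
  trainability and privacy transfer qualitatively, not quantitatively, to
  transformer backbones.
* The distillation guarantee is distributional: a student can only match
  its teacher where the public corpus exercises the teacher's behavior.
* Best F1 is in-sample optimistic by definition; compare against its null
  value, not across datasets of very different size.
* Bootstrap CIs are percentile intervals; they are known to be
  anti-conservative at perfectly-separated small samples (handled as above).
* The membership-inference attack is the protocol's simple logistic
  regression; stronger attacks (shadow models, likelihood ratios) are out
  of scope, so "student attack at chance" is evidence, not proof, of
  non-leakage.
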