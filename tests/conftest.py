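import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import oncodistill as od
from oncodistill.workflow import (
    default_experiment_config,
    run_distillation_experiment,
    run_privacy_experiment,
)


@pytest.fixture(scope="session")
def small_note_corpus():
    """A small, strongly-cued notes corpus for fast training tests."""
    cfg = od.GeneratorConfig(
        schema_name="NOTE_3", n_patients=240, docs_per_patient=1, seed=42
    )
    return od.generate_labeled_corpus(cfg)


@pytest.fixture(scope="session")
def small_split(small_note_corpus):
    patients = sorted({d.patient_id for d in small_note_corpus.documents})
    return od.split_cohort(patients, seed=7)


@pytest.fixture(scope="session")
def distillation_runs():
    """Three full runs of the default distillation experiment (the study
    conditions: 2000 private docs, 5000 public docs, cue fidelity 0.9)."""
    return [
        run_distillation_experiment(default_experiment_config(seed=seed))
        for seed in (0, 1, 2)
    ]


@pytest.fixture(scope="session")
def privacy_runs():
    """Five full runs of the membership-inference audit at the default
    settings (100 members, 100 nonmembers, 60/40 split)."""
    return [
        run_privacy_experiment(default_experiment_config(seed=seed))
        for seed in range(5)
    ]
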