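"""Shared fixtures: synthetic sessions and cohorts at test-friendly scale.

Everything is generated programmatically and seeded; heavyweight
cohorts are session-scoped so the expensive generation and feature
extraction run once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from premac import synthetic_data as sd
from premac.features import FeatureConfig, build_feature_matrix
from premac.labeling import assign_labels, concat_labeled


def extract_subject(subject, window_s: float = 90.0):
    """Feature+label pipeline for one subject; returns (dataset, pairs)."""
    parts, pairs = [], []
    cfg = FeatureConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # precursor-free control sessions
        for s in subject.sessions:
            fm = build_feature_matrix(s.streams, cfg)
            parts.append(assign_labels(fm, s.log, window_s, subject.subject_id))
            pairs.append((fm, s.log))
    return concat_labeled(parts, subject.subject_id), pairs


@pytest.fixture(scope="session")
def small_subject():
    """One subject at 35% session length: quick, still a few precursors."""
    return sd.generate_subject(sd.SubjectProfile(seed=11, duration_scale=0.35))


@pytest.fixture(scope="session")
def accept_cohort():
    """Three-subject heterogeneous cohort at half session length."""
    return sd.generate_cohort(3, heterogeneity=1.0, seed=7, duration_scale=0.5)


@pytest.fixture(scope="session")
def accept_data(accept_cohort):
    """Labeled datasets and per-session (features, log) pairs per subject."""
    datasets, pairs = [], []
    for subj in accept_cohort:
        d, p = extract_subject(subj)
        datasets.append(d)
        pairs.append(p)
    return datasets, pairs


@pytest.fixture(scope="session")
def accept_indiv_accuracies(accept_data):
    """Per-subject individualized RF accuracies (computed once)."""
    from premac import models

    datasets, _ = accept_data
    return [models.crossval_individual(d, "rf", seed=0).accuracy
            for d in datasets]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
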