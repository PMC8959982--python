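"""Shared fixtures.

Small cohorts (reduced sampling rate and duration) keep unit tests
fast; the full default cohort — 20 + 20 subjects, 8 channels, 80 s at
1 kHz, four segments — is built once per session for the end-to-end
classification checks.
"""

import numpy as np
import pytest

from plvnet import CohortSpec, generate_cohort
from plvnet.connectivity import BinaryNetwork
from plvnet.pipeline import compute_sample_bank, feature_tables_from_bank


def make_network(adj, labels=None, threshold=0.5, band="alpha"):
    adj = np.asarray(adj)
    labels = labels or tuple(f"n{i}" for i in range(adj.shape[0]))
    return BinaryNetwork(adjacency=adj, threshold=threshold,
                         node_labels=tuple(labels), band=band)


def complete_network(n=8):
    return make_network(np.ones((n, n), dtype=int) - np.eye(n, dtype=int))


@pytest.fixture
def small_spec():
    """Tiny cohort for fast end-to-end unit tests."""
    return CohortSpec(n_per_group=2, fs=250.0, duration=24.0,
                      noise_sd=0.3, seed=7)


@pytest.fixture(scope="session")
def default_cohort_tables():
    """Feature tables of the full default synthetic cohort at the 0.71
    threshold: the study conditions for classification checks."""
    spec = CohortSpec(seed=1)
    bank = compute_sample_bank(generate_cohort(spec))
    return feature_tables_from_bank(bank, threshold=0.71)
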