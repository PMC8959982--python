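"""Wavelet phase extraction, PLV, binarization and network diagnostics."""

import networkx as nx
import numpy as np
import pytest

from conftest import complete_network, make_network
from plvnet import (binarize, connectivity_matrix, get_band,
                    instantaneous_phase, plv, sparsity_bounds,
                    sparsity_lower_bound)
from plvnet.connectivity import ConnectivityMatrix
from plvnet.preprocessing import Segment


def _seg(data, fs=250.0, labels=None):
    labels = labels or tuple(f"ch{i}" for i in range(data.shape[0]))
    return Segment(data=data, fs=fs, segment_index=0, subject_id="s0",
                   group="A", channel_labels=labels)


def _tone(freq, fs, seconds, phase=0.0):
    t = np.arange(0, seconds, 1 / fs)
    return np.cos(2 * np.pi * freq * t + phase)


def test_tone_phase_advances_linearly():
    fs = 500.0
    tone = _tone(10.0, fs, 8.0)[np.newaxis]
    ph = instantaneous_phase(_seg(tone, fs), get_band("alpha"))
    inc = np.diff(np.unwrap(ph[0]))[1000:-1000]
    # the Morlet center sits at 10.5 Hz but a pure 10 Hz tone still has
    # constant 10 Hz phase velocity under the wavelet's analytic signal
    assert np.abs(inc - 2 * np.pi * 10.0 / fs).max() < 1e-3


def test_identical_channels_identical_phase():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(4000)
    ph = instantaneous_phase(_seg(np.vstack([x, x])), get_band("alpha"))
    assert np.array_equal(ph[0], ph[1])


def test_quarter_period_delay_gives_half_pi_offset():
    fs = 1000.0
    x = _tone(10.0, fs, 10.0)
    y = _tone(10.0, fs, 10.0, phase=-np.pi / 2)  # quarter-period delay
    ph = instantaneous_phase(_seg(np.vstack([x, y]), fs), get_band("alpha"))
    diff = np.angle(np.exp(1j * (ph[0] - ph[1])))[2000:-2000]
    assert np.abs(diff - np.pi / 2).max() < 0.02


@pytest.mark.parametrize("case, expected", [
    ("identical", 1.0), ("offset", 1.0), ("alternating", 0.0)])
def test_plv_analytic_cases(case, expected):
    n = 1000
    base = np.linspace(-np.pi, np.pi, n)
    if case == "identical":
        val = plv(base, base)
    elif case == "offset":
        val = plv(base, base - np.pi / 2)
    else:
        other = base + np.where(np.arange(n) % 2 == 0, 0.0, np.pi)
        val = plv(base, other)
    assert abs(val - expected) < 1e-12


def test_plv_rejects_mismatched_lengths():
    with pytest.raises(ValueError, match="equal length"):
        plv(np.zeros(10), np.zeros(11))


def test_plv_null_matches_analytic_mean():
    """E|mean of n unit phasors| = sqrt(pi)/(2 sqrt(n)) for uniform phases."""
    rng = np.random.default_rng(1)
    n, reps = 200, 1000
    vals = [plv(rng.uniform(-np.pi, np.pi, n),
                rng.uniform(-np.pi, np.pi, n)) for _ in range(reps)]
    expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
    # null PLV has SD ~ sqrt((4-pi)/(4n)); allow 4 standard errors
    se = np.sqrt((4 - np.pi) / (4 * n)) / np.sqrt(reps)
    assert abs(np.mean(vals) - expected) < 4 * se


def test_plv_invariant_under_common_phase_shift():
    rng = np.random.default_rng(2)
    a = rng.uniform(-np.pi, np.pi, 500)
    b = rng.uniform(-np.pi, np.pi, 500)
    assert abs(plv(a, b) - plv(a + 1.234, b + 1.234)) < 1e-12


def test_connectivity_matrix_properties():
    rng = np.random.default_rng(3)
    data = rng.standard_normal((8, 8 * 250))
    cm = connectivity_matrix(_seg(data), get_band("alpha"))
    v = cm.values
    assert v.shape == (8, 8)
    assert np.allclose(v, v.T)
    assert np.allclose(np.diag(v), 1.0)
    assert v.min() >= 0 and v.max() <= 1


def test_connectivity_matrix_permutation_equivariance():
    rng = np.random.default_rng(4)
    data = rng.standard_normal((5, 2000))
    perm = [3, 1, 4, 0, 2]
    cm = connectivity_matrix(_seg(data), get_band("alpha"))
    cmp_ = connectivity_matrix(_seg(data[perm]), get_band("alpha"))
    assert np.allclose(cm.values[np.ix_(perm, perm)], cmp_.values, atol=1e-12)


def test_connectivity_matrix_rejects_bad_input():
    with pytest.raises(ValueError, match="2 channels"):
        connectivity_matrix(_seg(np.zeros((1, 2000))), get_band("alpha"))
    bad = np.zeros((2, 2000))
    bad[0, 5] = np.nan
    with pytest.raises(ValueError, match="finite"):
        connectivity_matrix(_seg(bad), get_band("alpha"))


def _cm(values):
    v = np.asarray(values, dtype=float)
    return ConnectivityMatrix(values=v, band=get_band("alpha"),
                              channel_labels=tuple(
                                  f"n{i}" for i in range(v.shape[0])))


def test_binarize_threshold_rules():
    n = 8
    high = np.full((n, n), 0.9)
    np.fill_diagonal(high, 1.0)
    net = binarize(_cm(high), 0.71)
    assert net.n_edges == 28  # complete graph K8
    assert binarize(_cm(high), 0.91).n_edges == 0
    mixed = np.full((n, n), 0.5)
    mixed[0, 1] = mixed[1, 0] = 0.8
    np.fill_diagonal(mixed, 1.0)
    net = binarize(_cm(mixed), 0.71)
    assert net.n_edges == 1 and net.adjacency[0, 1] == 1
    # ties at exactly the threshold are excluded
    tie = np.full((n, n), 0.71)
    np.fill_diagonal(tie, 1.0)
    assert binarize(_cm(tie), 0.71).n_edges == 0


def test_binarize_monotone_in_threshold():
    rng = np.random.default_rng(5)
    for _ in range(20):
        v = rng.uniform(0, 1, (6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            adj = binarize(_cm(v), thr).adjacency
            if prev is not None:
                assert np.all(adj <= prev)  # raising threshold drops edges
            prev = adj


def test_binarize_rejects_bad_threshold():
    v = np.eye(3)
    for thr in (0.0, 1.0, -0.2, 1.5):
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            binarize(_cm(v), thr)


def test_sparsity_lower_bound_value():
    assert abs(sparsity_lower_bound(8) - 2 * np.log(8) / 8) < 1e-12
    assert abs(sparsity_lower_bound(8) - 0.5199) < 1e-4


def test_sparsity_diagnostics_complete_and_empty():
    diag = sparsity_bounds(complete_network(8))
    assert diag.density == 1.0 and diag.passes_lower_bound
    empty = make_network(np.zeros((8, 8), dtype=int))
    diag = sparsity_bounds(empty)
    assert diag.density == 0.0 and not diag.passes_lower_bound
    assert not diag.passes_small_world


def test_small_world_ring_with_shortcuts():
    g = nx.watts_strogatz_graph(20, 6, 0.1, seed=42)
    net = make_network(nx.to_numpy_array(g, dtype=int))
    diag = sparsity_bounds(net, n_null=50, seed=0)
    assert diag.sigma > 1
    assert diag.passes_small_world
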