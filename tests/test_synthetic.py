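"""Synthetic cohort generator: determinism, planted structure, EDF I/O."""

import numpy as np
import pytest
from scipy import stats

from plvnet import (CohortSpec, generate_cohort, generate_subject,
                    get_band, read_edf, write_edf, welch_psd, band_ratios)
from plvnet.bands import BAND_ORDER, DEFAULT_BANDS
from plvnet.connectivity import instantaneous_phase, plv
from plvnet.preprocessing import Segment, select_channels
from plvnet.synthetic import DEFAULT_CHANNELS


def _coupling(alpha_c=0.0, pair=(0, 1), n_ch=8):
    out = {}
    for g in ("A", "B"):
        per_band = {b: np.zeros((n_ch, n_ch)) for b in BAND_ORDER}
        per_band["alpha"][pair[0], pair[1]] = alpha_c
        per_band["alpha"][pair[1], pair[0]] = alpha_c
        out[g] = per_band
    return out


def _alpha_plv(rec, i=0, j=1):
    seg = Segment(data=rec.data, fs=rec.fs, segment_index=0,
                  subject_id=rec.subject_id, group=rec.group,
                  channel_labels=rec.channel_labels)
    ph = instantaneous_phase(seg, get_band("alpha"))
    trim = int(rec.fs)
    return plv(ph[i, trim:-trim], ph[j, trim:-trim])


def test_generation_is_deterministic(small_spec):
    a = generate_subject(small_spec, "A", 0)
    b = generate_subject(small_spec, "A", 0)
    assert np.array_equal(a.data, b.data)
    c1 = generate_cohort(small_spec)
    c2 = generate_cohort(small_spec)
    assert all(np.array_equal(x.data, y.data) for x, y in zip(c1, c2))


def test_subjects_and_groups_differ(small_spec):
    a0 = generate_subject(small_spec, "A", 0)
    a1 = generate_subject(small_spec, "A", 1)
    b0 = generate_subject(small_spec, "B", 0)
    assert not np.array_equal(a0.data, a1.data)
    assert not np.array_equal(a0.data, b0.data)


@pytest.mark.parametrize("n_per_group, expected", [(20, 40), (2, 4)])
def test_cohort_is_balanced(n_per_group, expected):
    spec = CohortSpec(n_per_group=n_per_group, fs=250.0, duration=2.0)
    cohort = generate_cohort(spec)
    assert len(cohort) == expected
    assert sum(r.group == "A" for r in cohort) == n_per_group
    assert len({r.subject_id for r in cohort}) == expected


def test_unknown_group_rejected(small_spec):
    with pytest.raises(ValueError, match="A"):
        generate_subject(small_spec, "Z", 0)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError, match="n_per_group"):
        CohortSpec(n_per_group=1, fs=250.0, duration=2.0).validate()
    bad = _coupling(alpha_c=1.5)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        CohortSpec(fs=250.0, duration=2.0, coupling=bad).validate()


def test_perfect_coupling_forces_phase_identity():
    # alpha-only signal: neighbouring bands would otherwise leak into
    # the wavelet's passband and blur the shared alpha phase
    bp = {g: {"alpha": 1.0} for g in ("A", "B")}
    spec = CohortSpec(n_per_group=2, fs=250.0, duration=20.0, noise_sd=0.0,
                      band_power=bp, coupling=_coupling(alpha_c=1.0), seed=3)
    rec = generate_subject(spec, "A", 0)
    assert _alpha_plv(rec, 0, 1) > 0.999


def test_zero_coupling_gives_near_null_plv():
    spec = CohortSpec(n_per_group=2, fs=250.0, duration=20.0, noise_sd=0.0,
                      coupling=_coupling(alpha_c=0.0), seed=3)
    vals = [_alpha_plv(generate_subject(spec, "A", i)) for i in range(2)]
    # narrowband phases decorrelate over ~1/bandwidth; uncoupled PLV stays
    # far below the strongly coupled regime
    assert max(vals) < 0.5


def test_coupling_monotonically_raises_plv():
    """Mean PLV over replicate subjects is non-decreasing in coupling."""
    means = []
    for c in (0.1, 0.5, 0.9):
        spec = CohortSpec(n_per_group=17, fs=250.0, duration=12.0,
                          noise_sd=0.2, coupling=_coupling(alpha_c=c),
                          seed=5)
        vals = [_alpha_plv(generate_subject(spec, "A", i))
                for i in range(17)]
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_group_alpha_power_contrast():
    """Group A's reduced alpha amplitude yields lower alpha band ratio
    (sign test over 20 subject pairs, p < 0.01)."""
    spec = CohortSpec(n_per_group=20, fs=250.0, duration=12.0, seed=9)
    cohort = generate_cohort(spec)
    bands = list(DEFAULT_BANDS.values())
    ratios = {}
    for rec in cohort:
        ratios[rec.subject_id] = band_ratios(welch_psd(rec), bands)["alpha"]
    wins = sum(ratios[f"A{i:02d}"] < ratios[f"B{i:02d}"] for i in range(20))
    p = stats.binomtest(wins, 20, 0.5, alternative="greater").pvalue
    assert p < 0.01


def test_edf_round_trip(tmp_path, small_spec):
    rec = generate_subject(small_spec, "B", 1)
    path = write_edf(rec, tmp_path / "B01.edf")
    back = read_edf(path, group="B")
    assert back.fs == rec.fs
    assert back.channel_labels == rec.channel_labels
    step = 2 * np.abs(rec.data).max() / 65535
    n = min(rec.n_samples, back.n_samples)
    assert np.abs(back.data[:, :n] - rec.data[:, :n]).max() <= step


def test_edf_extra_channel_subset(tmp_path, small_spec):
    rec = generate_subject(small_spec, "A", 0)
    from plvnet.synthetic import EEGRecording
    extra = EEGRecording(
        data=np.vstack([rec.data, rec.data[:1]]),
        fs=rec.fs, channel_labels=rec.channel_labels + ("EXTRA",),
        subject_id=rec.subject_id, group=rec.group)
    path = write_edf(extra, tmp_path / "x.edf")
    back = read_edf(path)
    sel = select_channels(back, list(DEFAULT_CHANNELS))
    assert sel.channel_labels == DEFAULT_CHANNELS
    with pytest.raises(ValueError, match="O9"):
        select_channels(back, ["FP1", "O9"])
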