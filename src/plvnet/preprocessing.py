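"""Resting-state EEG preprocessing.

The pipeline applied to every recording: common average reference,
zero-phase 0.1-30 Hz band-pass, selection of the highest-SNR 80-second
window, per-channel z-scoring, equal split into four 20-second segments,
channel subsetting, and zero-phase per-band filtering.

All filters are 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), so no phase distortion is introduced — essential,
since downstream connectivity is phase-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .bands import BandDefinition
from .synthetic import EEGRecording

BROADBAND = (0.1, 30.0)
#: Band used by the signal-to-noise proxy for window selection.
SNR_BAND = (0.5, 30.0)


@dataclass
class Segment:
    """A contiguous slice of one subject's preprocessed recording,
    optionally tagged with the band it has been filtered to."""

    data: np.ndarray
    fs: float
    segment_index: int
    subject_id: str
    group: str
    band: BandDefinition | None = None
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 4):
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs,
                         output="sos")


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous across-channel mean from every sample."""
    return data - data.mean(axis=0, keepdims=True)


def _best_window_start(data: np.ndarray, fs: float, window_samples: int,
                       stride_seconds: float = 1.0) -> int:
    """Start index of the sliding window maximising the SNR proxy:
    in-band (0.5-30 Hz) power as a fraction of total power."""
    n = data.shape[1]
    if n == window_samples:
        return 0
    sos = _bandpass_sos(*SNR_BAND, fs)
    inband = signal.sosfiltfilt(sos, data, axis=1)
    num = np.concatenate([[0.0], np.cumsum((inband ** 2).sum(axis=0))])
    den = np.concatenate([[0.0], np.cumsum((data ** 2).sum(axis=0))])
    stride = max(1, int(round(stride_seconds * fs)))
    starts = np.arange(0, n - window_samples + 1, stride)
    e_in = num[starts + window_samples] - num[starts]
    e_tot = den[starts + window_samples] - den[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(e_tot > 0, e_in / e_tot, 0.0)
    return int(starts[np.argmax(score)])


def preprocess(rec: EEGRecording, window_seconds: float = 80.0) -> EEGRecording:
    """Average-reference, band-pass 0.1-30 Hz, keep the best
    ``window_seconds`` window, and z-score each channel over it."""
    window_samples = int(round(window_seconds * rec.fs))
    if rec.n_samples < window_samples:
        raise ValueError(
            f"recording {rec.subject_id!r} has {rec.n_samples / rec.fs:.1f} s, "
            f"needs at least {window_seconds:.1f} s"
        )
    data = average_reference(rec.data)
    # steeper broadband stage so mains (50 Hz) is fully rejected
    filtered = signal.sosfiltfilt(_bandpass_sos(*BROADBAND, rec.fs, order=8),
                                  data, axis=1)
    start = _best_window_start(data, rec.fs, window_samples)
    window = filtered[:, start : start + window_samples]
    sd = window.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    window = (window - window.mean(axis=1, keepdims=True)) / sd
    return EEGRecording(
        data=window,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        subject_id=rec.subject_id,
        group=rec.group,
    )


def split_segments(rec: EEGRecording, n_segments: int = 4) -> list[Segment]:
    """Split into equal-length contiguous segments, dropping any trailing
    remainder samples."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    seg_len = rec.n_samples // n_segments
    if seg_len == 0:
        raise ValueError("recording too short to split")
    return [
        Segment(
            data=rec.data[:, k * seg_len : (k + 1) * seg_len],
            fs=rec.fs,
            segment_index=k,
            subject_id=rec.subject_id,
            group=rec.group,
            channel_labels=rec.channel_labels,
        )
        for k in range(n_segments)
    ]


def select_channels(rec: EEGRecording, labels: list[str] | tuple[str, ...]) -> EEGRecording:
    """Reorder to the requested channel labels, dropping all others."""
    missing = [lbl for lbl in labels if lbl not in rec.channel_labels]
    if missing:
        raise ValueError(f"channels not present in recording: {missing}")
    idx = [rec.channel_labels.index(lbl) for lbl in labels]
    return EEGRecording(
        data=rec.data[idx],
        fs=rec.fs,
        channel_labels=tuple(labels),
        subject_id=rec.subject_id,
        group=rec.group,
    )


def bandpass_band(seg: Segment, band: BandDefinition) -> Segment:
    """Zero-phase band-pass a segment to one band and tag it."""
    if seg.fs <= 2 * band.hi:
        raise ValueError(
            f"band {band.name} (hi={band.hi} Hz) violates Nyquist at fs={seg.fs}"
        )
    filtered = signal.sosfiltfilt(_bandpass_sos(band.lo, band.hi, seg.fs),
                                  seg.data, axis=1)
    return Segment(
        data=filtered,
        fs=seg.fs,
        segment_index=seg.segment_index,
        subject_id=seg.subject_id,
        group=seg.group,
        band=band,
        channel_labels=seg.channel_labels,
    )
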