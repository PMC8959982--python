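"""Synthetic two-group EEG cohort generator.

Emulates an eight-channel resting-state recording setup (FP1, FP2, C3,
C4, T3, T4, O1, O2 at 1 kHz) for two subject groups with controllable
per-band amplitude and pairwise phase coupling, so that every downstream
stage — spectral analysis, phase-locking connectivity, network metrics
and classification — can be exercised without patient data.

Generative model
----------------
Each channel is a sum over the five classical bands of unit-variance
narrow-band Gaussian processes (white noise band-pass filtered to the
band), scaled by a per-group band amplitude. Pairwise phase coupling in
a band is imposed by mixing a shared narrow-band driver into both
channels of the pair::

    u_i = sqrt(1 - sum_j c_ij) * private_i + sum_j sqrt(c_ij) * shared_ij

where ``c_ij`` in [0, 1] is the coupling strength. ``c_ij = 1`` makes
the pair's band signals identical (downstream PLV = 1); ``c_ij = 0``
leaves them independent. Row sums of the coupling matrix (diagonal
excluded) must not exceed 1 so that band variance stays at 1.

Every random process draws from its own deterministic substream keyed by
``(seed, group, subject, band, role, i, j)``, so changing one coupling
entry never perturbs the noise realisations of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .bands import BAND_ORDER, DEFAULT_BANDS, BandDefinition, canonical_band_name

DEFAULT_CHANNELS = ("FP1", "FP2", "C3", "C4", "T3", "T4", "O1", "O2")

#: Homologous left/right electrode pairs used by the default coupling layout.
HOMOLOGOUS_PAIRS = ((0, 1), (2, 3), (4, 5), (6, 7))

#: Base signal scale in microvolts for a unit-amplitude band.
BASE_AMPLITUDE_UV = 10.0


def default_band_power() -> dict[str, dict[str, float]]:
    """Group band-amplitude scalars: group A with elevated slow-wave
    (delta, theta x1.5) and suppressed alpha (x0.6) relative to group B."""
    return {
        "A": {"delta": 1.5, "theta": 1.5, "alpha": 0.6, "beta1": 1.0, "beta2": 1.0},
        "B": {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta1": 1.0, "beta2": 1.0},
    }


def default_coupling(n_channels: int = 8) -> dict[str, dict[str, np.ndarray]]:
    """Group coupling matrices: homologous pairs weakly coupled (0.3) in
    every band, with a strong alpha contrast — 0.9 in group B versus 0.4
    in group A — so that alpha-band phase locking separates the groups."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for group in ("A", "B"):
        per_band = {}
        for band in BAND_ORDER:
            c = np.zeros((n_channels, n_channels))
            strength = 0.3
            if band == "alpha":
                strength = 0.9 if group == "B" else 0.4
            for i, j in HOMOLOGOUS_PAIRS:
                if i < n_channels and j < n_channels:
                    c[i, j] = c[j, i] = strength
            per_band[band] = c
        out[group] = per_band
    return out


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    ``band_power[group][band]`` are relative amplitude scalars and
    ``coupling[group][band]`` symmetric channel x channel matrices of
    pairwise phase-coupling strengths in [0, 1] (diagonal ignored).
    """

    n_per_group: int = 20
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    fs: float = 1000.0
    duration: float = 80.0
    band_power: dict[str, dict[str, float]] = field(default_factory=default_band_power)
    coupling: dict[str, dict[str, np.ndarray]] = field(default_factory=default_coupling)
    noise_sd: float = 0.5
    seed: int = 0

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.band_power)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        highest = max(DEFAULT_BANDS[b].hi for b in BAND_ORDER)
        if self.fs <= 2 * highest:
            raise ValueError(f"fs must exceed 2 x {highest} Hz")
        n_ch = len(self.channels)
        for group, per_band in self.coupling.items():
            for band, c in per_band.items():
                canonical_band_name(band)
                c = np.asarray(c)
                if c.shape != (n_ch, n_ch):
                    raise ValueError(
                        f"coupling[{group}][{band}] must be {n_ch}x{n_ch}"
                    )
                off = c - np.diag(np.diag(c))
                if not np.allclose(off, off.T):
                    raise ValueError(f"coupling[{group}][{band}] must be symmetric")
                if off.min() < 0 or off.max() > 1:
                    raise ValueError(
                        f"coupling[{group}][{band}] entries must lie in [0, 1]"
                    )
                if (off.sum(axis=1) > 1 + 1e-12).any():
                    raise ValueError(
                        f"coupling[{group}][{band}]: per-channel coupling "
                        "(row sums) must not exceed 1"
                    )
        for group, per_band in self.band_power.items():
            for band in per_band:
                canonical_band_name(band)


@dataclass
class EEGRecording:
    """One subject's multichannel time series (microvolts, channels x samples)."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data must be (n_channels={len(self.channel_labels)}, n_samples), "
                f"got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _substream(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(keys)))


def _group_code(group: str) -> int:
    return zlib.crc32(group.encode("utf-8"))


def _narrowband(rng: np.random.Generator, n: int, band: BandDefinition,
                fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the given band."""
    sos = signal.butter(4, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def generate_subject(spec: CohortSpec, group: str, subject_index: int) -> EEGRecording:
    """Generate one subject's recording; deterministic in (seed, group, index)."""
    spec.validate()
    if group not in spec.groups:
        raise ValueError(
            f"unknown group {group!r}; valid groups: {sorted(spec.groups)}"
        )
    if not 0 <= subject_index < spec.n_per_group:
        raise ValueError("subject_index must lie in [0, n_per_group)")

    n_ch, n = len(spec.channels), spec.n_samples
    gc = _group_code(group)
    data = np.zeros((n_ch, n))

    for b_idx, band_name in enumerate(BAND_ORDER):
        band = DEFAULT_BANDS[band_name]
        amp = spec.band_power[group].get(band_name, 0.0)
        if amp == 0:
            continue
        c = np.asarray(spec.coupling[group].get(band_name, np.zeros((n_ch, n_ch))))
        off = c - np.diag(np.diag(c))

        shared: dict[tuple[int, int], np.ndarray] = {}
        for i in range(n_ch):
            for j in range(i + 1, n_ch):
                if off[i, j] > 0:
                    rng = _substream(spec.seed, gc, subject_index, b_idx, 1, i, j)
                    shared[(i, j)] = _narrowband(rng, n, band, spec.fs)

        for i in range(n_ch):
            row = off[i].sum()
            rng = _substream(spec.seed, gc, subject_index, b_idx, 0, i, i)
            u = np.sqrt(max(0.0, 1.0 - row)) * _narrowband(rng, n, band, spec.fs)
            for (a, b), s in shared.items():
                if i in (a, b):
                    u = u + np.sqrt(off[a, b]) * s
            data[i] += amp * u

    if spec.noise_sd > 0:
        rng = _substream(spec.seed, gc, subject_index, 99, 2, 0, 0)
        data += spec.noise_sd * rng.standard_normal((n_ch, n))

    return EEGRecording(
        data=BASE_AMPLITUDE_UV * data,
        fs=spec.fs,
        channel_labels=spec.channels,
        subject_id=f"{group}{subject_index:02d}",
        group=group,
    )


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """Generate the full balanced cohort: n_per_group subjects per group."""
    spec.validate()
    return [
        generate_subject(spec, group, idx)
        for group in spec.groups
        for idx in range(spec.n_per_group)
    ]


# ---------------------------------------------------------------------------
# EDF export / import
# ---------------------------------------------------------------------------

def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording to an EDF (16-bit) file.

    Uses 1-second data records; trailing samples that do not fill a whole
    record are dropped. Physical range is set symmetrically from the data
    so the quantisation step is ``2 * max|x| / 65535`` microvolts.
    """
    path = Path(path)
    fs_int = int(round(rec.fs))
    if abs(fs_int - rec.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = rec.n_samples // fs_int
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_rec * fs_int]
    ns = rec.n_channels

    pmax = float(np.abs(data).max())
    pmax = pmax if pmax > 0 else 1.0
    pmin = -pmax
    dmin, dmax = -32768, 32767
    # digital = (phys - pmin) / step + dmin, the exact inverse of the EDF
    # reader's reconstruction, so round-trip error is at most half a step
    step = (pmax - pmin) / (dmax - dmin)
    digital = np.clip(np.round((data - pmin) / step) + dmin, dmin, dmax).astype("<i2")

    def pad(value: str, width: int) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8),                               # version
        pad(f"X X X {rec.subject_id}", 80),        # patient id
        pad(f"Startdate X X X X group={rec.group}", 80),  # recording id
        pad("01.01.00", 8), pad("00.00.00", 8),    # start date / time
        pad(str(256 * (1 + ns)), 8),               # header bytes
        pad("", 44),                               # reserved
        pad(str(n_rec), 8),                        # number of data records
        pad("1", 8),                               # record duration (s)
        pad(str(ns), 4),                           # number of signals
    ])
    sig = b"".join([
        b"".join(pad(lbl, 16) for lbl in rec.channel_labels),
        b"".join(pad("EEG", 80) for _ in range(ns)),          # transducer
        b"".join(pad("uV", 8) for _ in range(ns)),            # physical dim
        b"".join(pad(f"{-pmax:.6g}", 8) for _ in range(ns)),  # physical min
        b"".join(pad(f"{pmax:.6g}", 8) for _ in range(ns)),   # physical max
        b"".join(pad(str(dmin), 8) for _ in range(ns)),       # digital min
        b"".join(pad(str(dmax), 8) for _ in range(ns)),       # digital max
        b"".join(pad("", 80) for _ in range(ns)),             # prefiltering
        b"".join(pad(str(fs_int), 8) for _ in range(ns)),     # samples/record
        b"".join(pad("", 32) for _ in range(ns)),             # reserved
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            chunk = digital[:, r * fs_int : (r + 1) * fs_int]
            fh.write(chunk.tobytes())  # channel-sequential within record
    return path


def read_edf(path: str | Path, group: str = "unknown") -> EEGRecording:
    """Read an EDF file into an EEGRecording (microvolts)."""
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise ValueError(f"failed to parse EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne stores volts
    subject_id = path.stem
    info_sid = (raw.info.get("subject_info") or {}).get("his_id")
    if info_sid:
        subject_id = str(info_sid).split()[-1]
    return EEGRecording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject_id=subject_id,
        group=group,
    )
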