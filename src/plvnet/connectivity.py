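"""Phase-locking-value functional connectivity and network binarization.

Instantaneous phase per band is taken from the complex Morlet wavelet
coefficient at the band's center frequency (7 cycles). The PLV between
two channels is the modulus of the time-averaged unit phasor of their
phase difference:

    PLV = | < exp(i (θ_x(t) - θ_y(t))) > |

which is 1 for perfectly locked phases and has null expectation
sqrt(pi) / (2 sqrt(n)) for n independent phase samples. Binary networks
keep edges whose PLV strictly exceeds a threshold; diagnostics check
the random-graph connectivity bound 2 ln(N) / N and the small-world
coefficient sigma against degree-preserving rewired nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .bands import BandDefinition
from .preprocessing import Segment

#: Morlet cycles used for phase extraction.
N_CYCLES = 7.0
#: Seconds discarded at each segment end before averaging phasors
#: (wavelet edge effects).
EDGE_TRIM_SECONDS = 1.0


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel PLV matrix in [0, 1], unit diagonal."""

    values: np.ndarray
    band: BandDefinition
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    segment_index: int = -1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        self.values = v


@dataclass
class BinaryNetwork:
    """Thresholded undirected adjacency (zero diagonal) with provenance."""

    adjacency: np.ndarray
    threshold: float
    node_labels: tuple[str, ...]
    band: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def to_graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.node_labels)))


def morlet_phases(data: np.ndarray, fs: float,
                  center_freqs: list[float]) -> np.ndarray:
    """Instantaneous phase (radians, (-pi, pi]) of each channel at each
    Morlet center frequency; returns (n_freqs, n_channels, n_samples)."""
    from mne.time_frequency import tfr_array_morlet

    for f in center_freqs:
        if f >= fs / 2:
            raise ValueError(f"center frequency {f} Hz violates Nyquist (fs={fs})")
    data = np.asarray(data, dtype=np.float64)
    out = tfr_array_morlet(
        data[np.newaxis], sfreq=fs, freqs=np.asarray(center_freqs, float),
        n_cycles=N_CYCLES, output="phase", verbose="error",
    )
    return np.transpose(out[0], (1, 0, 2))


def instantaneous_phase(seg: Segment, band: BandDefinition) -> np.ndarray:
    """Per-channel phase series from the wavelet coefficient at the
    band's center frequency; shape (n_channels, n_samples)."""
    if seg.fs <= 2 * band.hi:
        raise ValueError(f"band {band.name} violates Nyquist at fs={seg.fs}")
    return morlet_phases(seg.data, seg.fs, [band.center])[0]


def plv(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase-locking value between two equal-length phase series."""
    phase_x = np.asarray(phase_x, float).ravel()
    phase_y = np.asarray(phase_y, float).ravel()
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series must have equal length")
    if phase_x.size < 2:
        raise ValueError("need at least 2 phase samples")
    return float(np.abs(np.exp(1j * (phase_x - phase_y)).mean()))


def plv_matrix_from_phases(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLV from a (n_channels, n_samples) phase array."""
    z = np.exp(1j * phases)
    m = np.abs(z @ z.conj().T) / phases.shape[1]
    m = np.clip(m, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return (m + m.T) / 2


def connectivity_matrix(seg: Segment, band: BandDefinition,
                        edge_trim: float = EDGE_TRIM_SECONDS) -> ConnectivityMatrix:
    """Pairwise PLV matrix of one segment in one band, discarding
    ``edge_trim`` seconds at each end before averaging phasors."""
    if seg.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if not np.isfinite(seg.data).all():
        raise ValueError("segment contains non-finite samples")
    phases = instantaneous_phase(seg, band)
    trim = int(round(edge_trim * seg.fs))
    if 2 * trim >= phases.shape[1]:
        raise ValueError("edge trim leaves no samples")
    if trim:
        phases = phases[:, trim:-trim]
    labels = tuple(getattr(seg, "channel_labels", ()) or
                   (f"ch{i}" for i in range(seg.n_channels)))
    return ConnectivityMatrix(
        values=plv_matrix_from_phases(phases),
        band=band,
        channel_labels=labels,
        subject_id=seg.subject_id,
        segment_index=seg.segment_index,
    )


def binarize(cm: ConnectivityMatrix, threshold: float) -> BinaryNetwork:
    """Edges where PLV strictly exceeds the threshold; diagonal zeroed."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    adj = (cm.values > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(
        adjacency=adj,
        threshold=threshold,
        node_labels=tuple(cm.channel_labels),
        band=cm.band.name,
    )


@dataclass
class SparsityDiagnostics:
    """Edge density vs the full-connectivity bound 2 ln(N)/N, and the
    small-world coefficient sigma vs degree-preserving rewired nulls."""

    density: float
    lower_bound: float
    passes_lower_bound: bool
    sigma: float
    passes_small_world: bool
    used_largest_component: bool
    notes: str = ""


def sparsity_lower_bound(n_nodes: int) -> float:
    """Minimum edge density 2 ln(N)/N for full connectivity of a random
    graph on N nodes."""
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    return 2.0 * np.log(n_nodes) / n_nodes


def _clustering_and_path(g: nx.Graph) -> tuple[float, float]:
    c = nx.average_clustering(g)
    l = nx.average_shortest_path_length(g) if g.number_of_nodes() > 1 else np.nan
    return c, l


def sparsity_bounds(net: BinaryNetwork, n_null: int = 100,
                    seed: int = 0) -> SparsityDiagnostics:
    """Network sanity diagnostics; sigma = (C/C_rand) / (L/L_rand)."""
    n = net.n_nodes
    if n < 3:
        raise ValueError("need at least 3 nodes")
    bound = sparsity_lower_bound(n)
    density = net.n_edges / (n * (n - 1) / 2)

    g = net.to_graph()
    used_lcc = False
    notes = ""
    if g.number_of_edges() == 0:
        return SparsityDiagnostics(density, bound, density >= bound,
                                   float("nan"), False, False, "empty graph")
    if not nx.is_connected(g):
        used_lcc = True
        notes = "sigma computed on largest connected component"
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    c_obs, l_obs = _clustering_and_path(g)

    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    n_edges = g.number_of_edges()
    for _ in range(n_null):
        gr = g.copy()
        if n_edges >= 2:
            try:
                nx.double_edge_swap(gr, nswap=4 * n_edges,
                                    max_tries=100 * n_edges,
                                    seed=int(rng.integers(2 ** 31)))
            except nx.NetworkXException:
                pass  # dense or rigid graph: keep the partial rewiring
        if not nx.is_connected(gr):
            gr = gr.subgraph(max(nx.connected_components(gr), key=len)).copy()
        c_r, l_r = _clustering_and_path(gr)
        c_null.append(c_r)
        l_null.append(l_r)
    c_rand, l_rand = float(np.mean(c_null)), float(np.mean(l_null))
    if c_rand <= 0 or l_rand <= 0 or not np.isfinite(l_obs):
        sigma = float("nan")
        notes = (notes + "; " if notes else "") + "sigma undefined for this graph"
    else:
        sigma = (c_obs / c_rand) / (l_obs / l_rand)
    return SparsityDiagnostics(
        density=density,
        lower_bound=bound,
        passes_lower_bound=density >= bound,
        sigma=sigma,
        passes_small_world=bool(np.isfinite(sigma) and sigma > 1),
        used_largest_component=used_lcc,
        notes=notes,
    )
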