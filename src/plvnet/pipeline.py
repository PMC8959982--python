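"""End-to-end orchestration: cohort -> preprocessing -> spectra -> PLV
networks -> graph metrics -> feature tables -> cross-validated
classification.

The expensive stages (phase extraction and PLV) are computed once into a
*sample bank*; binarization, metric extraction and classification are
cheap and re-run from the bank for any threshold, which is what makes
the 0.11-0.91 threshold sweep affordable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import (BAND_ORDER, DEFAULT_BANDS, MULTILAYER_BANDS,
                    canonical_band_name)
from .connectivity import (ConnectivityMatrix, binarize,
                           morlet_phases, plv_matrix_from_phases,
                           EDGE_TRIM_SECONDS)
from .features import (FeatureTable, cross_validate, run_comparison,
                       SELECTOR_KINDS, CLASSIFIER_KINDS)
from .metrics import METRIC_NAMES, multilayer_metrics, node_metrics
from .preprocessing import preprocess, select_channels, split_segments
from .spectral import channel_band_powers, welch_psd
from .synthetic import CohortSpec, EEGRecording, generate_cohort, read_edf

logger = logging.getLogger("plvnet")

CONDITIONS = ("PS", *BAND_ORDER, "MN", "IMN")


@dataclass
class SampleBank:
    """Per-sample (subject-segment) PLV matrices and spectral summaries."""

    subject_ids: list[str]
    groups: list[str]
    segment_indices: list[int]
    channel_labels: tuple[str, ...]
    plv: list[dict[str, ConnectivityMatrix]]     # band -> matrix, per sample
    band_powers: list[np.ndarray]                # (n_ch, n_bands), per sample
    band_names: tuple[str, ...] = BAND_ORDER

    @property
    def n_samples(self) -> int:
        return len(self.subject_ids)


def compute_sample_bank(records: list[EEGRecording],
                        channels: tuple[str, ...] | None = None,
                        window_seconds: float = 80.0,
                        n_segments: int = 4,
                        edge_trim: float = EDGE_TRIM_SECONDS) -> SampleBank:
    """Preprocess every recording, split it into segments, and compute
    each segment's Welch band powers and per-band PLV matrices."""
    bands = [DEFAULT_BANDS[b] for b in BAND_ORDER]
    centers = [b.center for b in bands]
    sids, grps, segs, plvs, powers = [], [], [], [], []
    labels: tuple[str, ...] = ()
    for rec in records:
        if channels is not None:
            rec = select_channels(rec, channels)
        labels = rec.channel_labels
        pre = preprocess(rec, window_seconds=window_seconds)
        for seg in split_segments(pre, n_segments):
            profile = welch_psd(seg)
            powers.append(channel_band_powers(profile))
            phases = morlet_phases(seg.data, seg.fs, centers)
            trim = int(round(edge_trim * seg.fs))
            per_band = {}
            for band, ph in zip(bands, phases):
                ph = ph[:, trim:-trim] if trim else ph
                per_band[band.name] = ConnectivityMatrix(
                    values=plv_matrix_from_phases(ph),
                    band=band,
                    channel_labels=labels,
                    subject_id=seg.subject_id,
                    segment_index=seg.segment_index,
                )
            sids.append(seg.subject_id)
            grps.append(seg.group)
            segs.append(seg.segment_index)
            plvs.append(per_band)
    return SampleBank(subject_ids=sids, groups=grps, segment_indices=segs,
                      channel_labels=labels, plv=plvs, band_powers=powers)


def _metric_row(prefix: str, nodes, metric_sets) -> dict[str, float]:
    row = {}
    for name in METRIC_NAMES:
        vals = metric_sets.as_dict()[name]
        for node, v in zip(nodes, vals):
            row[f"{prefix}|{name}|{node}"] = float(v)
    return row


def feature_tables_from_bank(bank: SampleBank, threshold: float = 0.71,
                             multilayer_bands: tuple[str, ...] = MULTILAYER_BANDS,
                             ) -> dict[str, FeatureTable]:
    """Build the eight feature conditions from a sample bank.

    PS: per-channel band powers plus whole-head band ratios over all five
    bands. Per-band conditions: the 4 node metrics x channels of that
    band's thresholded network. MN: unweighted node-wise sum over the
    multilayer bands; IMN: the same sum weighted by each sample's
    power-spectral ratios ∂ over those bands (∂ sum to 1).
    """
    ml_bands = tuple(canonical_band_name(b) for b in multilayer_bands)
    nodes = bank.channel_labels
    band_idx = {b: i for i, b in enumerate(bank.band_names)}
    rows: dict[str, list[dict]] = {c: [] for c in CONDITIONS}

    for s in range(bank.n_samples):
        layer_metrics = {}
        for band in bank.band_names:
            net = binarize(bank.plv[s][band], threshold)
            layer_metrics[band] = node_metrics(net, provenance=band)
            rows[band].append(_metric_row(band, nodes, layer_metrics[band]))

        layers = [layer_metrics[b] for b in ml_bands]
        rows["MN"].append(_metric_row("MN", nodes,
                                      multilayer_metrics(layers)))
        powers = bank.band_powers[s]
        ml_power = np.array([powers[:, band_idx[b]].mean() for b in ml_bands])
        total = ml_power.sum()
        weights = (ml_power / total if total > 0
                   else np.full(len(ml_bands), 1.0 / len(ml_bands)))
        rows["IMN"].append(_metric_row(
            "IMN", nodes, multilayer_metrics(layers, weights=weights)))

        ps_row = {}
        head_power = powers.mean(axis=0)
        ps_total = head_power.sum()
        for b, bname in enumerate(bank.band_names):
            for c, ch in enumerate(nodes):
                ps_row[f"PS|power|{bname}|{ch}"] = float(powers[c, b])
            ps_row[f"PS|ratio|{bname}"] = float(
                head_power[b] / ps_total if ps_total > 0 else 0.0)
        rows["PS"].append(ps_row)

    meta = dict(
        groups=pd.Series(bank.groups),
        subjects=pd.Series(bank.subject_ids),
        segments=pd.Series(bank.segment_indices),
    )
    return {
        cond: FeatureTable(values=pd.DataFrame(rows[cond]), **meta)
        for cond in CONDITIONS
    }


def threshold_sweep(bank: SampleBank,
                    thresholds: tuple[float, ...] = tuple(
                        np.round(np.arange(0.11, 0.92, 0.1), 2)),
                    condition: str = "alpha", classifier: str = "elts",
                    selector: str = "filter", k: int = 20,
                    k_folds: int = 10, seed: int = 0,
                    params: dict | None = None) -> pd.DataFrame:
    """CV accuracy of one feature condition at each binarization
    threshold; reports the argmax threshold alongside the table."""
    rows = []
    for thr in thresholds:
        tables = feature_tables_from_bank(bank, threshold=float(thr))
        res = cross_validate(tables[condition], kind=classifier,
                             selector=selector, k=k, k_folds=k_folds,
                             seed=seed, params=params)
        rows.append({"threshold": float(thr),
                     "mean_accuracy": res.mean_accuracy})
    df = pd.DataFrame(rows)
    df.attrs["best_threshold"] = float(
        df.loc[df["mean_accuracy"].idxmax(), "threshold"])
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

THRESHOLD_SWEEP_DEFAULT = tuple(np.round(np.arange(0.11, 0.92, 0.1), 2))


@dataclass
class RunConfig:
    """Fully-resolved configuration of one pipeline run."""

    n_per_group: int = 20
    fs: float = 1000.0
    duration: float = 80.0
    noise_sd: float = 0.5
    channels: tuple[str, ...] = ("FP1", "FP2", "C3", "C4",
                                 "T3", "T4", "O1", "O2")
    edf_dir: str | None = None
    n_segments: int = 4
    window_seconds: float = 80.0
    threshold: float | None = 0.71
    sweep: tuple[float, ...] | None = None
    multilayer_bands: tuple[str, ...] = MULTILAYER_BANDS
    selector: str = "filter"
    k: int = 20
    classifiers: tuple[str, ...] = ("elts",)
    folds: int = 10
    seed: int = 0
    out_dir: str = "runs"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None,
                    strict: bool = False) -> RunConfig:
    """Load a YAML config, apply defaults, and validate exhaustively.

    Raises ValueError carrying *all* problems found, not just the first.
    Unknown keys warn by default and fail under ``strict``.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
    raw.update(overrides or {})

    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    errors: list[str] = []
    if unknown:
        msg = f"unknown config keys: {unknown}"
        if strict:
            errors.append(msg)
        else:
            logger.warning(msg)
        raw = {k: v for k, v in raw.items() if k in known}

    for key in ("channels", "multilayer_bands", "classifiers", "sweep"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)

    if cfg.threshold is not None and cfg.sweep is not None:
        errors.append("threshold and sweep are mutually exclusive")
    if cfg.threshold is not None and not 0 < cfg.threshold < 1:
        errors.append(f"threshold must lie in (0, 1), got {cfg.threshold}")
    if cfg.sweep is not None and any(not 0 < t < 1 for t in cfg.sweep):
        errors.append("sweep thresholds must lie in (0, 1)")
    if cfg.n_per_group < 2:
        errors.append("n_per_group must be >= 2")
    if cfg.selector not in SELECTOR_KINDS:
        errors.append(f"unknown selector {cfg.selector!r}")
    for kind in cfg.classifiers:
        if kind not in CLASSIFIER_KINDS:
            errors.append(f"unknown classifier {kind!r}")
    if cfg.folds < 2:
        errors.append("folds must be >= 2")
    for b in cfg.multilayer_bands:
        try:
            canonical_band_name(b)
        except KeyError as exc:
            errors.append(str(exc))
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return cfg


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _load_records(cfg: RunConfig) -> list[EEGRecording]:
    if cfg.edf_dir:
        recs = []
        for f in sorted(Path(cfg.edf_dir).glob("*.edf")):
            group = "A" if f.stem.startswith("A") else "B"
            recs.append(read_edf(f, group=group))
        if not recs:
            raise ValueError(f"no EDF files found in {cfg.edf_dir}")
        return recs
    spec = CohortSpec(n_per_group=cfg.n_per_group, channels=cfg.channels,
                      fs=cfg.fs, duration=cfg.duration,
                      noise_sd=cfg.noise_sd, seed=cfg.seed)
    return generate_cohort(spec)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured run and write all stage outputs under a
    config-hash-named directory; returns that directory."""
    run_dir = Path(cfg.out_dir) / f"run-{cfg.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"config": asdict(cfg),
                                   "config_hash": cfg.config_hash(),
                                   "outputs": []}
    outputs: list[str] = manifest["outputs"]  # type: ignore[assignment]
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        logger.info(line)
        log_lines.append(line)

    def save(relpath: str, writer) -> None:
        p = run_dir / relpath
        p.parent.mkdir(parents=True, exist_ok=True)
        writer(p)
        outputs.append(relpath)

    stage = "simulate"
    try:
        records = _load_records(cfg)
        log(stage, f"{len(records)} recordings, "
                   f"{records[0].n_channels} channels x "
                   f"{records[0].n_samples} samples")
        save("cohort_manifest.csv", lambda p: pd.DataFrame([
            {"subject_id": r.subject_id, "group": r.group,
             "n_channels": r.n_channels, "n_samples": r.n_samples,
             "fs": r.fs} for r in records]).to_csv(p, index=False))

        stage = "connect"
        bank = compute_sample_bank(records, channels=cfg.channels,
                                   window_seconds=cfg.window_seconds,
                                   n_segments=cfg.n_segments)
        log(stage, f"{bank.n_samples} samples x {len(BAND_ORDER)} bands")
        for s in range(bank.n_samples):
            for band, cm in bank.plv[s].items():
                rel = (f"plv/{cm.subject_id}_seg{cm.segment_index}"
                       f"_{band}.csv")
                save(rel, lambda p, cm=cm: pd.DataFrame(
                    cm.values, index=cm.channel_labels,
                    columns=cm.channel_labels).to_csv(p))

        stage = "classify"
        if cfg.sweep is not None:
            sweep_df = threshold_sweep(bank, thresholds=cfg.sweep,
                                       classifier=cfg.classifiers[0],
                                       selector=cfg.selector, k=cfg.k,
                                       k_folds=cfg.folds, seed=cfg.seed)
            log(stage, f"sweep over {len(cfg.sweep)} thresholds, best "
                       f"{sweep_df.attrs['best_threshold']}")
            save("threshold_sweep.csv",
                 lambda p: sweep_df.to_csv(p, index=False))
        else:
            tables = feature_tables_from_bank(
                bank, threshold=cfg.threshold,
                multilayer_bands=cfg.multilayer_bands)
            for cond, table in tables.items():
                df = table.values.copy()
                df.insert(0, "subject_id", table.subjects)
                df.insert(1, "group", table.groups)
                df.insert(2, "segment", table.segments)
                save(f"features_{cond}.csv",
                     lambda p, df=df: df.to_csv(p, index=False))
            results = run_comparison(tables, kinds=cfg.classifiers,
                                     selector=cfg.selector, k=cfg.k,
                                     k_folds=cfg.folds, seeds=(cfg.seed,))
            log(stage, f"{len(results)} condition x classifier results")
            save("cv_results.json", lambda p: p.write_text(
                results.to_json(orient="records", indent=2)))
            save("cv_results.csv", lambda p: results.drop(
                columns="fold_accuracies").to_csv(p, index=False))
    except Exception as exc:
        (run_dir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        (run_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (run_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    outputs.append("run.log")
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir
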