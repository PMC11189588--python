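"""End-to-end pipeline: manifest -> band filter -> features -> SVM report.

Binds the avalanche, connectivity, and classification modules into the
full workflow: ROI series are band-pass filtered, subject-level feature
matrices (ATM or imaginary coherence) are extracted, the shuffle-split SVM
is run, and all artifacts are written with a reproducibility block (config
hash, seed, package versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import scipy.signal
import yaml

from . import __version__
from .avalanches import binarize, compute_atm, detect_avalanches
from .classification import (
    ClassificationReport,
    ClassifierConfig,
    FeatureSet,
    ImportanceMap,
    fit_predict_splits,
    importance,
    vectorize,
)
from .connectivity import SpectralParams, imcoh
from .containers import RoiTimeSeries
from .io import read_manifest, read_series, write_matrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "bandpass", "run_pipeline"]

#: Named band presets, in Hz.
BANDS = {
    "broadband": (3.0, 40.0),
    "narrowband": (3.0, 14.0),
}


@dataclass
class PipelineConfig:
    """Resolved configuration of one classification run.

    ``band`` is a preset name (``broadband`` 3-40 Hz, ``narrowband``
    3-14 Hz), a custom ``(f_lo, f_hi)`` pair, or ``None`` to skip
    filtering. ``feature_kind`` selects ATM or imaginary-coherence
    features.
    """

    feature_kind: str = "atm"
    band: str | tuple[float, float] | None = "broadband"
    threshold_z: float = 3.0
    bin_size: int = 1
    min_duration_bins: int = 2
    delta_bins: int = 1
    spectral: SpectralParams = field(default_factory=SpectralParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    truncate_s: float | None = None
    filter_order: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_kind not in ("atm", "imcoh"):
            raise ValueError("feature_kind must be 'atm' or 'imcoh'")

    def band_edges(self) -> tuple[float, float] | None:
        if self.band is None:
            return None
        if isinstance(self.band, str):
            if self.band not in BANDS:
                raise ValueError(
                    f"unknown band '{self.band}'; presets: {sorted(BANDS)}"
                )
            return BANDS[self.band]
        lo, hi = self.band
        return (float(lo), float(hi))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spectral = SpectralParams(**raw.pop("spectral", {}))
        classifier = ClassifierConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("classifier", {}).items()
        })
        band = raw.get("band", "broadband")
        if isinstance(band, list):
            raw["band"] = tuple(band)
        return cls(spectral=spectral, classifier=classifier, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band) if isinstance(self.band, tuple) else self.band
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    report: ClassificationReport
    importance: ImportanceMap | None
    features: FeatureSet
    config: PipelineConfig


def bandpass(ts: RoiTimeSeries, band: tuple[float, float], order: int = 4) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass, applied per segment."""
    lo, hi = band
    if not 0 < lo < hi < ts.fs / 2:
        raise ValueError(f"band {band} outside (0, {ts.fs / 2:g}) Hz")
    sos = scipy.signal.butter(order, (lo, hi), btype="bandpass", fs=ts.fs, output="sos")
    data = ts.data.copy()
    for a, b in ts.segment_bounds:
        data[:, a:b] = scipy.signal.sosfiltfilt(sos, data[:, a:b], axis=1)
    return RoiTimeSeries(
        data=data,
        fs=ts.fs,
        roi_labels=list(ts.roi_labels),
        segment_bounds=list(ts.segment_bounds),
        subject_id=ts.subject_id,
        group=ts.group,
    )


def _truncate(ts: RoiTimeSeries, duration_s: float) -> RoiTimeSeries:
    n = int(round(duration_s * ts.fs))
    if n >= ts.n_samples:
        return ts
    bounds = [(a, min(b, n)) for a, b in ts.segment_bounds if a < n]
    logger.info("subject %s truncated to %g s", ts.subject_id, duration_s)
    return RoiTimeSeries(
        data=ts.data[:, :n],
        fs=ts.fs,
        roi_labels=list(ts.roi_labels),
        segment_bounds=bounds,
        subject_id=ts.subject_id,
        group=ts.group,
    )


def load_cohort_series(manifest_path: str | Path) -> tuple[list[RoiTimeSeries], list[str]]:
    """Load all subjects of a manifest, checking alignment before compute.

    Validates that every file is readable, all subjects share the sampling
    rate and ROI labels, and the manifest contains exactly two groups with
    at least 4 subjects each.
    """
    manifest = read_manifest(manifest_path)
    counts = manifest["group"].value_counts()
    if len(counts) != 2:
        raise ValueError(f"manifest must contain exactly 2 groups, got {len(counts)}")
    if counts.min() < 4:
        raise ValueError("need >= 4 subjects per group")
    subjects, labels = [], []
    for _, row in manifest.iterrows():
        ts = read_series(row["path"])
        ts.subject_id = row["subject_id"]
        ts.group = row["group"]
        subjects.append(ts)
        labels.append(row["group"])
    ref = subjects[0]
    for ts in subjects[1:]:
        if ts.fs != ref.fs:
            raise ValueError(
                f"sampling rate mismatch: {ts.subject_id} has {ts.fs}, "
                f"{ref.subject_id} has {ref.fs}"
            )
        if list(ts.roi_labels) != list(ref.roi_labels):
            raise ValueError(f"ROI label mismatch for subject {ts.subject_id}")
    return subjects, labels


def extract_features(
    subjects: list[RoiTimeSeries],
    labels: list[str],
    config: PipelineConfig,
    out_dir: Path | None = None,
) -> FeatureSet:
    """Filter, extract per-subject matrices, optionally write them, vectorize."""
    from .avalanches import rebin

    band = config.band_edges()
    mats = []
    for ts in subjects:
        if config.truncate_s is not None:
            ts = _truncate(ts, config.truncate_s)
        if band is not None:
            ts = bandpass(ts, band, config.filter_order)
        if config.feature_kind == "atm":
            raster = binarize(ts, config.threshold_z)
            if config.bin_size > 1:
                raster = rebin(raster, config.bin_size)
            avs = [
                a
                for a in detect_avalanches(raster, config.min_duration_bins)
                if a.n_bins >= config.delta_bins + 1
            ]
            if not avs:
                raise ValueError(
                    f"subject '{ts.subject_id}': no usable avalanche at "
                    f"threshold {config.threshold_z}"
                )
            mat = compute_atm(
                avs, ts.n_rois, config.delta_bins, roi_labels=ts.roi_labels
            )
            meta = {
                "threshold_z": config.threshold_z,
                "bin_size": config.bin_size,
                "min_duration_bins": config.min_duration_bins,
                "subject_id": ts.subject_id,
            }
        else:
            params = config.spectral
            if band is not None:
                params = SpectralParams(
                    window_seconds=params.window_seconds,
                    overlap_fraction=params.overlap_fraction,
                    freq_resolution_hz=params.freq_resolution_hz,
                    time_bandwidth=params.time_bandwidth,
                    band=band,
                )
            mat = imcoh(ts, params)
            meta = {"subject_id": ts.subject_id}
        if out_dir is not None:
            write_matrix(
                mat, out_dir / f"{ts.subject_id}_{config.feature_kind}.tsv", meta
            )
        mats.append(mat)
    return vectorize(mats, labels)


def run_pipeline(
    config: PipelineConfig,
    manifest_path: str | Path,
    out_dir: str | Path | None = None,
    *,
    compute_importance: bool = True,
) -> PipelineResult:
    """Run manifest -> features -> classification -> importance.

    When ``out_dir`` is given, writes per-subject feature matrices, the
    JSON report, the importance TSV, and a plain-text log carrying the
    config hash and package versions.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    subjects, labels = load_cohort_series(manifest_path)
    features = extract_features(subjects, labels, config, out)
    cfg = config.classifier
    report = fit_predict_splits(features, cfg)
    imp = None
    if compute_importance:
        try:
            imp = importance(features, cfg, report=report)
        except ValueError as exc:
            logger.warning("importance unavailable: %s", exc)
    if out is not None:
        payload = report.to_dict()
        payload["reproducibility"] = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": cfg.seed,
            "avakit_version": __version__,
            "numpy_version": np.__version__,
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2))
        if imp is not None:
            edge_labels = features.edge_labels()
            with open(out / "importance.tsv", "w") as fh:
                fh.write("edge\timportance\n")
                for lab, v in zip(edge_labels, imp.edge_importance):
                    fh.write(f"{lab}\t{v:.8g}\n")
                fh.write("\n")
                names = features.roi_labels or [
                    str(i) for i in range(imp.node_importance.size)
                ]
                fh.write("node\timportance\n")
                for lab, v in zip(names, imp.node_importance):
                    fh.write(f"{lab}\t{v:.8g}\n")
    return PipelineResult(report=report, importance=imp, features=features, config=config)
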