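"""Classification accuracy as a function of the signal length used for ATMs.

Short recordings average few avalanches, so transition-matrix estimates
are noisy and classification suffers; with growing window length the
accuracy rises toward the full-recording value. This module quantifies
that dependence: for each window length, windows are placed at random
positions in each subject's recording, the whole ATM-classification
pipeline runs per placement, and per cross-validation split the median
accuracy over placements is recorded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .avalanches import binarize, compute_atm, detect_avalanches
from .classification import ClassifierConfig, fit_predict_splits, vectorize
from .containers import BinaryRaster, RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = ["WindowAnalysisResult", "window_accuracy", "plot_window_accuracy"]


@dataclass
class WindowAnalysisResult:
    """Per-length distributions of the median-over-placements accuracy.

    ``per_length[L]`` is an array with one entry per cross-validation
    split: the median over the random window placements of that split's
    test accuracy.
    """

    lengths_s: list[float]
    per_length: dict[float, np.ndarray]
    n_placements: int
    seed: int

    def mean_accuracy(self) -> dict[float, float]:
        return {L: float(v.mean()) for L, v in self.per_length.items()}

    def to_dict(self) -> dict:
        return {
            "lengths_s": self.lengths_s,
            "n_placements": self.n_placements,
            "seed": self.seed,
            "per_length": {str(L): v.tolist() for L, v in self.per_length.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _slice_raster(raster: BinaryRaster, start: int, n_bins: int) -> BinaryRaster:
    """Contiguous window of a raster, with segment bounds intersected."""
    stop = start + n_bins
    bounds = []
    for a, b in raster.segment_bounds:
        lo, hi = max(a, start), min(b, stop)
        if hi > lo:
            bounds.append((lo - start, hi - start))
    return BinaryRaster(
        bits=raster.bits[:, start:stop],
        fs=raster.fs,
        bin_size=raster.bin_size,
        threshold_z=raster.threshold_z,
        segment_bounds=bounds,
        roi_labels=raster.roi_labels,
    )


def window_accuracy(
    subjects: Sequence[RoiTimeSeries],
    labels: Sequence[str],
    lengths_s: Sequence[float],
    cfg: ClassifierConfig,
    *,
    n_placements: int = 100,
    threshold_z: float = 3.0,
    min_duration_bins: int = 2,
    delta_bins: int = 1,
    seed: int | None = None,
) -> WindowAnalysisResult:
    """Median-over-placements classification accuracy per window length.

    Each subject is binarized once over the full recording (so the
    z-scoring is window-independent); for every length and placement a
    contiguous window is drawn uniformly per subject, ATMs are computed
    from that window only, and the full shuffle-split classification runs.
    Placements are i.i.d. across subjects and placements share nothing but
    the seed policy. Avalanche parameters are held fixed across lengths.

    When a placement leaves some subject without a usable avalanche, that
    placement is skipped for all lengths' bookkeeping (logged); the
    windows are long enough in practice that this is rare.

    Raises
    ------
    ValueError
        If some window length exceeds a subject's recording (named).
    """
    if seed is None:
        seed = cfg.seed
    if n_placements < 1:
        raise ValueError("n_placements must be >= 1")
    max_len = max(lengths_s)
    for ts in subjects:
        if ts.duration_s < max_len:
            raise ValueError(
                f"subject '{ts.subject_id}' has {ts.duration_s:g} s < "
                f"window of {max_len:g} s"
            )
    rasters = [binarize(ts, threshold_z) for ts in subjects]
    n_rois = subjects[0].n_rois
    roi_labels = list(subjects[0].roi_labels)
    rng = np.random.default_rng(seed)
    per_length: dict[float, np.ndarray] = {}
    for L in lengths_s:
        n_bins = int(round(L * subjects[0].fs))
        acc_matrix = []  # (placement, split)
        for p in range(n_placements):
            mats = []
            ok = True
            for raster in rasters:
                start = int(rng.integers(0, raster.n_bins - n_bins + 1))
                window = _slice_raster(raster, start, n_bins)
                avs = [
                    a
                    for a in detect_avalanches(window, min_duration_bins)
                    if a.n_bins >= delta_bins + 1
                ]
                if not avs:
                    ok = False
                    break
                mats.append(
                    compute_atm(avs, n_rois, delta_bins, roi_labels=roi_labels)
                )
            if not ok:
                logger.warning(
                    "length %gs placement %d skipped: a subject had no avalanche",
                    L,
                    p,
                )
                continue
            features = vectorize(mats, labels)
            report = fit_predict_splits(features, cfg)
            acc_matrix.append(report.metric_values("accuracy"))
        if not acc_matrix:
            raise ValueError(f"no usable placement at window length {L} s")
        per_length[float(L)] = np.median(np.array(acc_matrix), axis=0)
    return WindowAnalysisResult(
        lengths_s=[float(L) for L in lengths_s],
        per_length=per_length,
        n_placements=n_placements,
        seed=seed,
    )


def plot_window_accuracy(result: WindowAnalysisResult, path: str | None = None):
    """Strip plot of the per-split accuracy distribution per window length."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    rng = np.random.default_rng(0)
    for k, L in enumerate(result.lengths_s):
        vals = result.per_length[L]
        jitter = rng.uniform(-0.15, 0.15, size=vals.size)
        ax.plot(np.full(vals.size, k) + jitter, vals, "o", alpha=0.5, ms=4)
        ax.plot(k, vals.mean(), "k_", ms=18)
    ax.set_xticks(range(len(result.lengths_s)))
    ax.set_xticklabels([f"{L:g}" for L in result.lengths_s])
    ax.set_xlabel("window length (s)")
    ax.set_ylabel("accuracy (median over placements)")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
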