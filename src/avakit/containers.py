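"""In-memory containers for ROI-level time series and binarized rasters.

A recording is a 2-D ``(n_rois, n_samples)`` array plus a sampling rate and
region labels. Because upstream artifact rejection may excise epochs, a
recording carries explicit *segment bounds*: an ordered list of half-open
sample intervals marking contiguous stretches of signal. All avalanche and
spectral computations respect those discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RoiTimeSeries", "BinaryRaster", "validate_segments"]


def validate_segments(segments: list[tuple[int, int]], n_samples: int, min_len: int = 1) -> None:
    """Check that segments are ordered, non-overlapping, and cover [0, n_samples)."""
    if not segments:
        raise ValueError("segment list is empty")
    prev_end = 0
    for start, end in segments:
        if start != prev_end:
            raise ValueError(
                f"segments must tile the recording: gap/overlap at sample {start} "
                f"(expected {prev_end})"
            )
        if end - start < min_len:
            raise ValueError(f"segment [{start}, {end}) shorter than {min_len} samples")
        prev_end = end
    if prev_end != n_samples:
        raise ValueError(f"segments end at {prev_end} but the recording has {n_samples} samples")


@dataclass
class RoiTimeSeries:
    """Continuous multichannel source activity.

    Parameters
    ----------
    data : ndarray, shape (n_rois, n_samples)
        Source-amplitude time courses, one row per region of interest.
    fs : float
        Sampling rate in Hz.
    roi_labels : list of str
        Ordered region names, one per row.
    segment_bounds : list of (int, int), optional
        Half-open sample intervals of contiguous signal. Defaults to one
        segment covering the whole recording.
    subject_id : str
        Identifier used in manifests and reports.
    group : str or None
        Optional class label (e.g. ``"patient"`` / ``"control"``).
    """

    data: np.ndarray
    fs: float
    roi_labels: list[str]
    segment_bounds: list[tuple[int, int]] | None = None
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_rois, n_samples) array")
        n_rois, n_samples = self.data.shape
        if n_rois < 2:
            raise ValueError("at least 2 ROIs are required")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if len(self.roi_labels) != n_rois:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {n_rois} ROIs"
            )
        if self.segment_bounds is None:
            self.segment_bounds = [(0, n_samples)]
        self.segment_bounds = [(int(a), int(b)) for a, b in self.segment_bounds]
        validate_segments(self.segment_bounds, n_samples, min_len=2)

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BinaryRaster:
    """Thresholded, binned {0, 1} activity matrix.

    ``bits[r, t] == 1`` means ROI ``r`` had a supra-threshold excursion
    somewhere inside bin ``t``. ``bin_size`` counts original samples per
    bin, so one bin spans ``bin_size / fs`` seconds.
    """

    bits: np.ndarray
    fs: float
    bin_size: int = 1
    threshold_z: float | None = None
    segment_bounds: list[tuple[int, int]] | None = None
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a 2-D (n_rois, n_bins) array")
        uniq = np.unique(self.bits)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.bits = self.bits.astype(np.uint8)
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.segment_bounds is None:
            self.segment_bounds = [(0, self.bits.shape[1])]
        self.segment_bounds = [(int(a), int(b)) for a, b in self.segment_bounds]
        if self.bits.shape[1] > 0:
            validate_segments(self.segment_bounds, self.bits.shape[1], min_len=1)

    @property
    def n_rois(self) -> int:
        return self.bits.shape[0]

    @property
    def n_bins(self) -> int:
        return self.bits.shape[1]

    @property
    def bin_duration_s(self) -> float:
        return self.bin_size / self.fs
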