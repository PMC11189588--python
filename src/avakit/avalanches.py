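"""Neuronal avalanche detection, branching-ratio estimation, and transition
matrices.

The workflow mirrors the standard large-scale avalanche analysis of
source-level electrophysiology:

1. z-score each ROI over time and mark excursions beyond a threshold
   (both signs) as active (:func:`binarize`);
2. optionally coarsen the time axis (:func:`rebin`);
3. segment *avalanches* — maximal runs of contiguous bins with at least one
   active ROI, bounded by fully silent bins (:func:`detect_avalanches`);
4. estimate the branching ratio sigma, the geometric-mean ratio of event
   counts in successive bins, averaged geometrically over avalanches
   (:func:`branching_ratio`); sigma ~ 1 marks critical dynamics and guides
   the choice of bin size (:func:`select_bin_size`);
5. summarize propagation as an avalanche transition matrix (ATM), whose
   (i, j) entry estimates the probability that ROI j is active one lag
   after ROI i within an avalanche (:func:`compute_atm`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import BinaryRaster, RoiTimeSeries

__all__ = [
    "Avalanche",
    "BranchingEstimate",
    "TransitionMatrix",
    "binarize",
    "rebin",
    "detect_avalanches",
    "branching_ratio_avalanche",
    "branching_ratio",
    "select_bin_size",
    "compute_atm",
]


@dataclass
class Avalanche:
    """One contiguous supra-threshold event.

    ``[start_bin, end_bin)`` is a half-open interval in the raster's bin
    coordinates. ``active_sets[j]`` holds the indices of ROIs active in the
    j-th bin of the avalanche, and ``events_per_bin[j]`` its size (>= 1).
    """

    start_bin: int
    end_bin: int
    active_sets: list[np.ndarray]
    events_per_bin: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.end_bin - self.start_bin < 1:
            raise ValueError("an avalanche spans at least one bin")
        if len(self.active_sets) != self.end_bin - self.start_bin:
            raise ValueError("one active set per bin is required")
        self.active_sets = [np.asarray(s, dtype=np.intp) for s in self.active_sets]
        counts = np.array([s.size for s in self.active_sets], dtype=np.int64)
        if (counts < 1).any():
            raise ValueError("every bin of an avalanche has at least one active ROI")
        self.events_per_bin = counts

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    @property
    def size(self) -> int:
        """Total number of activations across the avalanche."""
        return int(self.events_per_bin.sum())


@dataclass
class BranchingEstimate:
    """Branching ratio sigma with its per-avalanche components.

    ``sigma`` is the geometric mean of ``sigma_per_avalanche`` over the
    ``n_avalanches`` avalanches of duration >= 2 bins that entered the
    product.
    """

    sigma_per_avalanche: np.ndarray
    sigma: float
    n_avalanches: int
    bin_size: int = 1


@dataclass
class TransitionMatrix:
    """Avalanche transition matrix (ATM).

    ``probs[i, j]`` is the estimated probability that ROI ``j`` is active at
    bin ``t + delta_bins`` given ROI ``i`` active at bin ``t``, averaged
    element-wise over avalanches. Rows of ROIs that never served as
    ancestors are all zero. ``ancestor_counts[i]`` counts (avalanche, bin)
    pairs in which ROI ``i`` was an ancestor.
    """

    probs: np.ndarray
    delta_bins: int
    n_avalanches_averaged: int
    ancestor_counts: np.ndarray
    roi_labels: list[str] | None = None


def binarize(ts: RoiTimeSeries, threshold_z: float) -> BinaryRaster:
    """Threshold z-scored activity into a {0, 1} raster at bin size 1.

    Each ROI is z-scored over the full recording (all segments
    concatenated); a sample is active when ``|z| > threshold_z``, i.e.
    positive and negative excursions both count.

    Raises
    ------
    ValueError
        If ``threshold_z <= 0``, or an ROI has zero variance (named in the
        message), either globally or within a segment.
    """
    if not threshold_z > 0:
        raise ValueError("threshold_z must be positive")
    data = ts.data
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd[:, 0] == 0)
    if flat.size:
        raise ValueError(f"ROI '{ts.roi_labels[flat[0]]}' has zero variance")
    for a, b in ts.segment_bounds:
        seg_sd = data[:, a:b].std(axis=1)
        flat = np.flatnonzero(seg_sd == 0)
        if flat.size:
            raise ValueError(
                f"ROI '{ts.roi_labels[flat[0]]}' has zero variance in segment [{a}, {b})"
            )
    z = (data - mean) / sd
    bits = (np.abs(z) > threshold_z).astype(np.uint8)
    return BinaryRaster(
        bits=bits,
        fs=ts.fs,
        bin_size=1,
        threshold_z=float(threshold_z),
        segment_bounds=list(ts.segment_bounds),
        roi_labels=list(ts.roi_labels),
    )


def rebin(raster: BinaryRaster, bin_size: int) -> BinaryRaster:
    """Collapse consecutive groups of ``bin_size`` samples into single bins.

    A ROI is active in the coarse bin if it was active in any constituent
    sample (logical OR). Binning restarts at every segment boundary, and a
    trailing partial bin within a segment is dropped rather than padded.
    Expects a bin-size-1 raster.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if raster.bin_size != 1:
        raise ValueError("rebin expects a raster at bin size 1")
    if bin_size == 1:
        return raster
    chunks: list[np.ndarray] = []
    new_bounds: list[tuple[int, int]] = []
    pos = 0
    for a, b in raster.segment_bounds:
        n_full = (b - a) // bin_size
        if n_full == 0:
            continue
        block = raster.bits[:, a : a + n_full * bin_size]
        coarse = block.reshape(raster.n_rois, n_full, bin_size).max(axis=2)
        chunks.append(coarse)
        new_bounds.append((pos, pos + n_full))
        pos += n_full
    if not chunks:
        raise ValueError("bin_size longer than every segment: empty rebinned raster")
    return BinaryRaster(
        bits=np.concatenate(chunks, axis=1),
        fs=raster.fs,
        bin_size=bin_size,
        threshold_z=raster.threshold_z,
        segment_bounds=new_bounds,
        roi_labels=raster.roi_labels,
    )


def detect_avalanches(
    raster: BinaryRaster,
    min_duration_bins: int = 1,
    *,
    drop_edge_runs: bool = True,
) -> list[Avalanche]:
    """Segment maximal runs of bins with >= 1 active ROI into avalanches.

    Runs are computed independently within each segment, so no avalanche
    spans a recording discontinuity. Runs touching a segment edge are
    incomplete (their true onset or offset was not observed) and are
    discarded when ``drop_edge_runs`` is true. Runs shorter than
    ``min_duration_bins`` are discarded. Output is ordered by start bin.
    """
    if min_duration_bins < 1:
        raise ValueError("min_duration_bins must be >= 1")
    active = raster.bits.any(axis=0)
    out: list[Avalanche] = []
    for a, b in raster.segment_bounds:
        seg = active[a:b]
        if seg.size == 0:
            continue
        # Run boundaries from sign changes of the padded activity indicator.
        padded = np.diff(np.concatenate(([0], seg.view(np.uint8), [0])).astype(np.int8))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            if drop_edge_runs and (s == 0 or e == seg.size):
                continue
            if e - s < min_duration_bins:
                continue
            cols = raster.bits[:, a + s : a + e]
            sets = [np.flatnonzero(cols[:, j]) for j in range(e - s)]
            out.append(Avalanche(start_bin=a + s, end_bin=a + e, active_sets=sets))
    return out


def branching_ratio_avalanche(av: Avalanche) -> float:
    """Branching ratio sigma_i of a single avalanche.

    The geometric mean over successive bin pairs of the descendant/ancestor
    event-count ratio,

        sigma_i = prod_{j=1}^{N-1} (n(j+1) / n(j)) ** (1 / (N - 1)),

    which telescopes to ``(n(N) / n(1)) ** (1 / (N - 1))``; the closed form
    is used directly.
    """
    n = av.events_per_bin
    if n.size < 2:
        raise ValueError("branching ratio needs an avalanche of >= 2 bins")
    return float((n[-1] / n[0]) ** (1.0 / (n.size - 1)))


def branching_ratio(avalanches: list[Avalanche], bin_size: int = 1) -> BranchingEstimate:
    """Geometric-mean branching ratio over all avalanches of >= 2 bins.

    Single-bin avalanches carry no ancestor/descendant pair and are
    excluded from the product.
    """
    sigmas = np.array(
        [branching_ratio_avalanche(av) for av in avalanches if av.n_bins >= 2]
    )
    if sigmas.size == 0:
        raise ValueError("no avalanche with >= 2 bins: branching ratio undefined")
    sigma = float(np.exp(np.mean(np.log(sigmas))))
    return BranchingEstimate(
        sigma_per_avalanche=sigmas,
        sigma=sigma,
        n_avalanches=int(sigmas.size),
        bin_size=bin_size,
    )


def select_bin_size(
    raster: BinaryRaster,
    candidate_bins: list[int],
    min_duration_bins: int = 1,
) -> int:
    """Pick the bin size whose branching ratio is closest to 1.

    Critical dynamics show sigma ~ 1; the candidate minimizing |sigma - 1|
    wins, with ties broken toward the smaller bin. Candidates that yield no
    usable avalanche are skipped with a warning.
    """
    if not candidate_bins:
        raise ValueError("candidate_bins is empty")
    best: tuple[float, int] | None = None
    for bs in sorted(candidate_bins):
        try:
            coarse = rebin(raster, bs)
            est = branching_ratio(
                detect_avalanches(coarse, min_duration_bins), bin_size=bs
            )
        except ValueError as exc:
            warnings.warn(f"bin size {bs} skipped: {exc}", stacklevel=2)
            continue
        dist = abs(est.sigma - 1.0)
        if best is None or dist < best[0]:
            best = (dist, bs)
    if best is None:
        raise ValueError("every candidate bin size yielded no usable avalanches")
    return best[1]


def compute_atm(
    avalanches: list[Avalanche],
    n_rois: int,
    delta_bins: int = 1,
    *,
    mode: str = "conditional",
    roi_labels: list[str] | None = None,
) -> TransitionMatrix:
    """Avalanche transition matrix averaged element-wise over avalanches.

    Within one avalanche, entry (i, j) is the conditional frequency

        #{t : i active at t, j active at t + delta} / #{t : i active at t},

    counting only bins with both ``t`` and ``t + delta`` inside the
    avalanche; rows of ROIs never active as ancestors are zero. The
    per-avalanche matrices are then averaged element-wise. With
    ``mode="binary"`` the per-avalanche matrix is instead the 0/1 indicator
    that the (i, j) transition occurred at least once.

    Avalanches shorter than ``delta_bins + 1`` bins contribute no ancestor
    bin and raise an error.
    """
    if not avalanches:
        raise ValueError("cannot compute an ATM from an empty avalanche list")
    if delta_bins < 1:
        raise ValueError("delta_bins must be >= 1")
    if mode not in ("conditional", "binary"):
        raise ValueError(f"unknown mode {mode!r}")
    acc = np.zeros((n_rois, n_rois))
    ancestor_counts = np.zeros(n_rois, dtype=np.int64)
    for av in avalanches:
        if av.n_bins < delta_bins + 1:
            raise ValueError(
                f"avalanche at bin {av.start_bin} has {av.n_bins} bins; "
                f"delta={delta_bins} needs at least {delta_bins + 1}"
            )
        num = np.zeros((n_rois, n_rois))
        den = np.zeros(n_rois)
        for t in range(av.n_bins - delta_bins):
            anc = av.active_sets[t]
            desc = av.active_sets[t + delta_bins]
            if anc.max() >= n_rois or desc.max() >= n_rois:
                raise ValueError("ROI index exceeds n_rois")
            den[anc] += 1
            num[np.ix_(anc, desc)] += 1
        ancestor_counts += den.astype(np.int64)
        rows = den > 0
        per_av = np.zeros((n_rois, n_rois))
        if mode == "conditional":
            per_av[rows] = num[rows] / den[rows, None]
        else:
            per_av[rows] = (num[rows] > 0).astype(float)
        acc += per_av
    probs = acc / len(avalanches)
    return TransitionMatrix(
        probs=probs,
        delta_bins=delta_bins,
        n_avalanches_averaged=len(avalanches),
        ancestor_counts=ancestor_counts,
        roi_labels=roi_labels,
    )
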