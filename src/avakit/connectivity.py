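"""Imaginary coherence from multitaper cross-spectral estimates.

The imaginary part of coherency,

    ImCoh_xy(f) = Im(S_xy(f)) / sqrt(S_xx(f) S_yy(f)),

is insensitive to instantaneous (zero-lag) mixing such as volume
conduction: any coupling that arrives with no time lag contributes only to
the real part of the cross-spectrum. Cross-spectra are estimated with
Welch-style averaging over sliding windows, each tapered with a family of
discrete prolate spheroidal sequences (DPSS) to trade variance against a
controlled spectral bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

from .containers import RoiTimeSeries

__all__ = ["SpectralParams", "ConnectivityMatrix", "cross_spectra", "imcoh"]


@dataclass
class SpectralParams:
    """Multitaper estimation settings.

    ``window_seconds`` and ``overlap_fraction`` control the Welch
    segmentation; ``time_bandwidth`` is the DPSS time-(half-)bandwidth
    product NW, with ``2 * NW - 1`` tapers used; ``band`` is the frequency
    band, in Hz, over which |ImCoh| is averaged. With 10 s windows the
    native frequency grid spacing is 0.1 Hz (``freq_resolution_hz`` is the
    guaranteed ceiling; no zero-padding is applied).
    """

    window_seconds: float = 10.0
    overlap_fraction: float = 0.5
    freq_resolution_hz: float = 0.1
    time_bandwidth: float = 4.0
    band: tuple[float, float] = (3.0, 40.0)

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if not self.window_seconds > 0:
            raise ValueError("window_seconds must be positive")
        f_lo, f_hi = self.band
        if not f_lo < f_hi:
            raise ValueError("band must satisfy f_lo < f_hi")
        if self.time_bandwidth < 1:
            raise ValueError("time_bandwidth must be >= 1")

    @property
    def n_tapers(self) -> int:
        return int(2 * self.time_bandwidth - 1)


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI-by-ROI connectivity with zero diagonal.

    ``values[x, y]`` is the band-averaged |ImCoh| between ROIs x and y
    (entries in [0, 1]); ``kind`` tags the estimator.
    """

    values: np.ndarray
    band: tuple[float, float]
    kind: str = "imcoh"
    roi_labels: list[str] | None = None


def _window_starts(segments: list[tuple[int, int]], nper: int, step: int) -> list[int]:
    starts: list[int] = []
    for a, b in segments:
        s = a
        while s + nper <= b:
            starts.append(s)
            s += step
    return starts


def cross_spectra(
    ts: RoiTimeSeries,
    params: SpectralParams,
    fmin: float | None = None,
    fmax: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper cross-spectral density matrix S_xy(f).

    Windows slide within each contiguous segment (never straddling a
    discontinuity) with the configured overlap; each window is mean-
    detrended, tapered with every DPSS in the family, Fourier transformed,
    and the outer products are averaged over tapers and windows with
    one-sided density scaling.

    Returns
    -------
    freqs : ndarray, shape (n_freqs,)
        Frequency grid in Hz, restricted to [fmin, fmax] when given.
    S : ndarray, shape (n_rois, n_rois, n_freqs), complex
        Cross-spectral densities; ``S[x, x]`` is real and nonnegative.

    Raises
    ------
    ValueError
        If no window fits inside any segment.
    """
    nper = int(round(params.window_seconds * ts.fs))
    if nper < 2:
        raise ValueError("window shorter than 2 samples")
    step = max(1, int(round(nper * (1 - params.overlap_fraction))))
    starts = _window_starts(ts.segment_bounds, nper, step)
    if not starts:
        raise ValueError(
            f"no {params.window_seconds:g}-s window fits inside any segment "
            f"(recording of {ts.duration_s:g} s)"
        )
    tapers = dpss(nper, params.time_bandwidth, Kmax=params.n_tapers)
    freqs = rfftfreq(nper, d=1.0 / ts.fs)
    keep = np.ones(freqs.size, dtype=bool)
    if fmin is not None:
        keep &= freqs >= fmin
    if fmax is not None:
        keep &= freqs <= fmax
    sel = np.flatnonzero(keep)
    freqs = freqs[sel]
    n = ts.n_rois
    S = np.zeros((n, n, freqs.size), dtype=complex)
    # One-sided PSD scaling per taper (tapers have unit energy).
    scale = 2.0 / ts.fs
    for s in starts:
        seg = ts.data[:, s : s + nper]
        seg = seg - seg.mean(axis=1, keepdims=True)
        for taper in tapers:
            spec = rfft(seg * taper, axis=1)[:, sel]
            S += scale * np.einsum("xf,yf->xyf", spec, np.conj(spec))
    S /= len(starts) * len(tapers)
    # Endpoint bins (DC/Nyquist) are not doubled in one-sided scaling.
    for f_idx, f in enumerate(freqs):
        if f == 0.0 or np.isclose(f, ts.fs / 2):
            S[:, :, f_idx] /= 2.0
    return freqs, S


def imcoh(
    ts: RoiTimeSeries,
    params: SpectralParams | None = None,
    *,
    signed: bool = False,
) -> ConnectivityMatrix:
    """Band-averaged imaginary coherence between all ROI pairs.

    Per grid frequency inside ``params.band``, coherency is normalized by
    the autospectra; the band value is the unweighted mean over those
    frequencies of |ImCoh| (or of signed ImCoh with ``signed=True``, in
    which case the matrix is antisymmetric). Diagonal is zero.

    Raises
    ------
    ValueError
        If the band exceeds the Nyquist range, or an autospectrum vanishes
        at a band frequency (ROI and frequency are named).
    """
    if params is None:
        params = SpectralParams()
    f_lo, f_hi = params.band
    if f_lo < 0 or f_hi > ts.fs / 2:
        raise ValueError(f"band {params.band} outside [0, {ts.fs / 2:g}] Hz")
    freqs, S = cross_spectra(ts, params, fmin=f_lo, fmax=f_hi)
    if freqs.size == 0:
        raise ValueError(f"no grid frequency falls inside band {params.band}")
    auto = np.einsum("xxf->xf", S).real
    bad = np.argwhere(auto <= 0)
    if bad.size:
        r, f_idx = bad[0]
        raise ValueError(
            f"zero autospectral density for ROI '{ts.roi_labels[r]}' at "
            f"{freqs[f_idx]:.2f} Hz"
        )
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    icoh = S.imag / denom
    values = icoh.mean(axis=2) if signed else np.abs(icoh).mean(axis=2)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(
        values=values,
        band=(f_lo, f_hi),
        kind="imcoh_signed" if signed else "imcoh",
        roi_labels=list(ts.roi_labels),
    )
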