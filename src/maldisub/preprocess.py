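"""Spectrum conditioning and centroid peak extraction.

Raw linear-mode profile spectra are smoothed (moving average), baseline
subtracted (rolling minimum followed by rolling mean), optionally
TIC-normalized, and reduced to a deduplicated centroid peak list.
Centroid-mode spectra (stick lists) skip conditioning and go straight to
deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import minimum_filter1d, uniform_filter1d

MAD_TO_SD = 1.4826  # normal-consistency factor for the median absolute deviation


@dataclass
class Spectrum:
    """One replicate's (m/z, intensity) trace or stick list with metadata.

    m/z must be strictly ascending; profile spectra need at least two points.
    """

    mz: np.ndarray
    intensity: np.ndarray
    strain_id: str = ""
    replicate: int = 0
    label: int | None = None
    centroid: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if not self.centroid and self.mz.size < 2:
            raise ValueError("profile spectrum needs at least 2 points")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly ascending")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class PeakList:
    """Centroided peaks of one spectrum: ascending m/z with intensity and SNR."""

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    strain_id: str = ""
    replicate: int = 0
    label: int | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (self.mz.shape == self.intensity.shape == self.snr.shape):
            raise ValueError("mz, intensity and snr must have the same length")
        if np.any(self.snr < 0):
            raise ValueError("snr must be non-negative")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("peak m/z values must be strictly ascending")

    def __len__(self) -> int:
        return self.mz.size


#: Convenience alias for a single (mz, intensity, snr) triple.
Peak = tuple[float, float, float]


def _window_points(mz: np.ndarray, window_da: float) -> int:
    """Convert a window in Da to an odd number of grid points (>= 3)."""
    spacing = float(np.median(np.diff(mz)))
    w = max(3, int(round(window_da / spacing)))
    return w + 1 if w % 2 == 0 else w


def _rolling_median(y: np.ndarray, window: int, stride: int = 64) -> np.ndarray:
    """Approximate rolling median: exact medians on a strided grid, linearly
    interpolated in between. Window and stride in points."""
    if y.size <= window:
        return np.full_like(y, float(np.median(y)))
    centers = np.arange(0, y.size, stride)
    half = window // 2
    meds = np.array([
        np.median(y[max(0, c - half): min(y.size, c + half + 1)]) for c in centers
    ])
    return np.interp(np.arange(y.size), centers, meds)


def condition_spectrum(
    s: Spectrum,
    smooth_window: int = 7,
    baseline_window: float = 500.0,
    normalize: bool = False,
) -> Spectrum:
    """Smooth, baseline-subtract and optionally TIC-normalize a profile spectrum.

    Parameters
    ----------
    s : Spectrum
        Profile-mode spectrum (centroid input raises, go straight to
        :func:`deduplicate_peaks` instead).
    smooth_window : int
        Moving-average window in grid points; 1 disables smoothing.
    baseline_window : float
        Width in Da of the rolling-minimum / rolling-mean baseline estimator.
    normalize : bool
        If true, scale so the total ion current (intensity sum) is 1.
    """
    if s.centroid:
        raise ValueError(
            "condition_spectrum expects a profile spectrum; centroid input "
            "should skip conditioning and go to deduplicate_peaks"
        )
    y = s.intensity.astype(float)
    if smooth_window > 1:
        y = uniform_filter1d(y, size=int(smooth_window), mode="nearest")
    w = _window_points(s.mz, baseline_window)
    baseline = uniform_filter1d(minimum_filter1d(y, size=w, mode="nearest"), size=w, mode="nearest")
    y = y - baseline
    # second, fine pass: the rolling minimum sits ~2-3 noise sd below the true
    # baseline and lags sloped backgrounds, leaving a slowly varying pedestal;
    # local-median centering removes it without touching peaks (peaks are far
    # narrower than the median window)
    w_med = _window_points(s.mz, baseline_window / 5.0)
    y = y - _rolling_median(y, w_med)
    y = np.clip(y, 0.0, None)
    if normalize:
        tic = y.sum()
        if tic > 0:
            y = y / tic
    return replace(s, intensity=y)


def pick_peaks(
    s: Spectrum,
    snr_min: float = 3.0,
    min_rel_intensity: float = 0.01,
) -> PeakList:
    """Detect local maxima in a conditioned profile spectrum and centroid them.

    A maximum is kept if it exceeds ``snr_min`` times the robust noise level
    (1.4826 x median absolute deviation of the trace) and
    ``min_rel_intensity`` times the base-peak intensity. The reported m/z is
    the intensity-weighted mean over the peak's FWHM span.

    An all-zero spectrum yields an empty peak list.
    """
    y = s.intensity
    base = float(y.max(initial=0.0))
    if base <= 0:
        empty = np.empty(0)
        return PeakList(empty, empty.copy(), empty.copy(), s.strain_id, s.replicate, s.label)
    med = float(np.median(y))
    noise = MAD_TO_SD * float(np.median(np.abs(y - med)))
    floor = max(snr_min * noise, min_rel_intensity * base)
    idx, _props = signal.find_peaks(y, height=floor)
    mzs, heights, snrs = [], [], []
    for i in idx:
        half = y[i] / 2.0
        lo = i
        while lo > 0 and y[lo - 1] >= half:
            lo -= 1
        hi = i
        while hi < y.size - 1 and y[hi + 1] >= half:
            hi += 1
        seg = slice(lo, hi + 1)
        weight = y[seg].sum()
        c = float((s.mz[seg] * y[seg]).sum() / weight) if weight > 0 else float(s.mz[i])
        mzs.append(c)
        heights.append(float(y[i]))
        snrs.append(float(y[i] / noise) if noise > 0 else np.inf)
    mz_arr = np.asarray(mzs)
    h_arr = np.asarray(heights)
    snr_arr = np.asarray(snrs)
    order = np.argsort(mz_arr)
    mz_arr, h_arr, snr_arr = mz_arr[order], h_arr[order], snr_arr[order]
    # two maxima inside one FWHM span can centroid to the same m/z; keep the taller
    if mz_arr.size > 1:
        uniq_mz, inverse = np.unique(mz_arr, return_inverse=True)
        if uniq_mz.size < mz_arr.size:
            h_u = np.zeros(uniq_mz.size)
            s_u = np.zeros(uniq_mz.size)
            np.maximum.at(h_u, inverse, h_arr)
            np.maximum.at(s_u, inverse, snr_arr)
            mz_arr, h_arr, snr_arr = uniq_mz, h_u, s_u
    return PeakList(mz_arr, h_arr, snr_arr, s.strain_id, s.replicate, s.label)


def deduplicate_peaks(p: PeakList, tol_ppm: float = 500.0) -> PeakList:
    """Merge peaks closer than ``tol_ppm`` into one.

    Single-linkage grouping on the sorted m/z list; each group is reported at
    its intensity-weighted mean m/z with the maximum member intensity (laser
    shot accumulation is already summed upstream, so max — not sum — is kept).
    Output peaks are guaranteed to be separated by more than the tolerance.
    """
    if len(p) == 0:
        return p
    mz, inten, snr = p.mz, p.intensity, p.snr
    gaps = np.diff(mz)
    # break between i and i+1 when the gap exceeds tol at the local mass
    breaks = np.nonzero(gaps > tol_ppm * 1e-6 * 0.5 * (mz[:-1] + mz[1:]))[0] + 1
    groups = np.split(np.arange(mz.size), breaks)
    out_mz, out_int, out_snr = [], [], []
    for g in groups:
        w = inten[g].sum()
        out_mz.append(float((mz[g] * inten[g]).sum() / w) if w > 0 else float(mz[g].mean()))
        out_int.append(float(inten[g].max()))
        out_snr.append(float(snr[g].max()))
    return PeakList(
        np.asarray(out_mz), np.asarray(out_int), np.asarray(out_snr),
        p.strain_id, p.replicate, p.label,
    )


def spectrum_to_peaklist(s: Spectrum) -> PeakList:
    """View a centroid-mode spectrum as a peak list (SNR unknown, set to inf)."""
    if not s.centroid:
        raise ValueError("spectrum_to_peaklist expects a centroid-mode spectrum")
    return PeakList(
        s.mz.copy(), s.intensity.copy(), np.full(s.mz.size, np.inf),
        s.strain_id, s.replicate, s.label,
    )


def write_spectrum_txt(s: Spectrum, path) -> None:
    """Write a spectrum as two-column tab-delimited text (m/z, intensity)."""
    np.savetxt(path, np.column_stack([s.mz, s.intensity]), fmt="%.6f", delimiter="\t")


def read_spectrum_txt(path, strain_id: str = "", replicate: int = 0,
                      label: int | None = None, centroid: bool = False) -> Spectrum:
    """Read a two-column tab-delimited (m/z, intensity) spectrum file."""
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    return Spectrum(data[:, 0], data[:, 1], strain_id, replicate, label, centroid)
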