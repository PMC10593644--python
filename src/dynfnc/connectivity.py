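"""Time-course cleaning, static FNC, and tapered sliding-window dynamic FNC.

Static FNC is the Pearson correlation of each component pair over the whole
scan, Fisher z-transformed (atanh) after capping |r| at 1 - 1e-7 so that
duplicated signals stay finite.  Dynamic FNC repeats the computation inside
a tapered sliding window: a rectangle of L TRs convolved with a Gaussian of
width sigma TRs, sliding in steps of one TR.  The taper weights enter the
correlation as observation weights (weighted means and covariances), which
preserves the correlation scale.  Temporal variability of a pair is the
sample standard deviation of its windowed values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sp_signal

from .containers import SFNCMatrix, TimeCourses, WindowedFNC, pair_indices
from .errors import ArgumentError, DegenerateDataError, InsufficientDataError

R_CAP = 1.0 - 1e-7  # |r| ceiling before atanh


@dataclass
class TaperedWindow:
    """Normalized taper over ``length`` TRs (weights >= 0, sum 1, symmetric)."""

    length: int
    sigma: float
    weights: np.ndarray


def _hampel(x: np.ndarray, threshold: float, window: int = 7) -> np.ndarray:
    """Replace samples deviating from the local median by > threshold robust
    SDs (1.4826 * MAD) with that local median.  Centered window, edges padded
    by reflection."""
    half = window // 2
    padded = np.pad(x, half, mode="reflect")
    views = sliding_window_view(padded, window)
    med = np.median(views, axis=1)
    mad = np.median(np.abs(views - med[:, None]), axis=1)
    scale = 1.4826 * mad
    dev = np.abs(x - med)
    out = x.copy()
    # where the local scale is 0 the neighbourhood is constant: any deviation is a spike
    spikes = np.where(scale > 0, dev > threshold * scale, dev > 0)
    out[spikes] = med[spikes]
    return out


def clean_timecourses(
    tcs: TimeCourses,
    despike_mad: float = 3.5,
    lowpass_hz: float = 0.15,
) -> TimeCourses:
    """Detrend, despike, and low-pass filter each component time course.

    Per component: remove the constant + linear trend, replace outliers
    beyond ``despike_mad`` robust deviations with the local median (Hampel
    filter, window 7), and apply a zero-phase 5th-order Butterworth low-pass
    at ``lowpass_hz``.
    """
    if tcs.tr_seconds <= 0:
        raise ArgumentError("tr_seconds must be positive")
    nyquist = 0.5 / tcs.tr_seconds
    if lowpass_hz >= nyquist:
        raise ArgumentError(f"low-pass cutoff {lowpass_hz} Hz >= Nyquist {nyquist} Hz")
    data = np.asarray(tcs.data, dtype=float)
    stds = data.std(axis=1)
    if np.any(stds == 0):
        bad = tcs.labels[int(np.argmax(stds == 0))]
        raise DegenerateDataError(f"component {bad} is constant")
    out = sp_signal.detrend(data, axis=1, type="linear")
    for c in range(out.shape[0]):
        out[c] = _hampel(out[c], despike_mad)
    sos = sp_signal.butter(5, lowpass_hz, btype="low", fs=1.0 / tcs.tr_seconds, output="sos")
    out = sp_signal.sosfiltfilt(sos, out, axis=1)
    return TimeCourses(
        subject=tcs.subject,
        session=tcs.session,
        data=out,
        tr_seconds=tcs.tr_seconds,
        labels=tcs.labels,
    )


def _fisher(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -R_CAP, R_CAP))


def static_fnc(tcs: TimeCourses) -> SFNCMatrix:
    """Whole-scan pairwise Pearson correlation, Fisher z-transformed."""
    if tcs.n_timepoints < 3:
        raise InsufficientDataError("need at least 3 time points for static FNC")
    data = tcs.data
    stds = data.std(axis=1)
    if np.any(stds == 0):
        bad = tcs.labels[int(np.argmax(stds == 0))]
        raise DegenerateDataError(f"component {bad} has zero variance")
    r = np.corrcoef(data)
    z = _fisher(r)
    np.fill_diagonal(z, np.nan)
    return SFNCMatrix(subject=tcs.subject, session=tcs.session, values=z, labels=tcs.labels)


def build_taper(L: int, sigma: float) -> TaperedWindow:
    """Tapered window: rectangle of width L convolved with a Gaussian.

    The Gaussian kernel is truncated at ±4 sigma; the convolution is cropped
    to its central L samples and renormalized to sum to one.
    """
    if L < 2:
        raise ArgumentError("window length must be >= 2 TRs")
    if sigma <= 0:
        raise ArgumentError("sigma must be positive")
    half = max(1, int(np.ceil(4.0 * sigma)))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-(x**2) / (2.0 * sigma**2))
    full = np.convolve(np.ones(L), kernel)
    start = (len(full) - L) // 2
    weights = full[start : start + L]
    weights = weights / weights.sum()
    return TaperedWindow(length=L, sigma=float(sigma), weights=weights)


def windowed_fnc(
    tcs: TimeCourses,
    window: TaperedWindow,
    step: int = 1,
    fisher_z: bool = True,
) -> WindowedFNC:
    """Sliding-window weighted correlation of every component pair.

    For each window start s in {0, step, 2*step, ...} up to T - L, compute
    the taper-weighted Pearson correlation of each pair over TRs
    [s, s + L), cap and (by default) Fisher-z transform.
    """
    L = window.length
    T = tcs.n_timepoints
    if T < L:
        raise InsufficientDataError(f"T={T} shorter than window length {L}")
    if step < 1:
        raise ArgumentError("step must be >= 1")
    w = window.weights
    views = sliding_window_view(tcs.data, L, axis=1)[:, ::step, :]  # (C, W, L)
    means = views @ w  # (C, W)
    centered = views - means[:, :, None]
    cov = np.einsum("awl,bwl,l->wab", centered, centered, w)
    var = np.einsum("waa->wa", cov)
    denom = np.sqrt(var[:, :, None] * var[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -R_CAP, R_CAP)
    vals = _fisher(r) if fisher_z else r
    ii, jj = pair_indices(tcs.n_components)
    starts = np.arange(0, T - L + 1, step)
    return WindowedFNC(
        subject=tcs.subject,
        session=tcs.session,
        values=vals[:, ii, jj],
        window_starts=starts,
        labels=tcs.labels,
        window_length=L,
        sigma=window.sigma,
        step=step,
        tr_seconds=tcs.tr_seconds,
        fisher_z=fisher_z,
    )


def fnc_variability(wfnc: WindowedFNC) -> np.ndarray:
    """Per-pair temporal variability: sample SD (ddof=1) across windows."""
    if wfnc.n_windows < 2:
        raise InsufficientDataError("need at least 2 windows for variability")
    return wfnc.values.std(axis=0, ddof=1)
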