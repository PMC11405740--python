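"""Continuous ECG / EDA / respiration traces to per-segment autonomic metrics.

ECG path: zero-phase fifth-order Butterworth high-pass at 0.5 Hz plus a
50 Hz power-line notch; QRS complexes are found from the steepness of the
signal gradient (candidate regions where |dV/dt| exceeds a sliding
median + c*MAD threshold), the R-peak being the local maximum within a
candidate region, with a 250 ms refractory period.  NN intervals deviating
more than a relative tolerance from a running median are flagged as
artifacts and excluded from metrics.

HRV time domain: MeanNN, SDNN (sample SD, n-1 denominator), RMSSD.
Frequency domain: the NN tachogram is cubic-spline interpolated to a
uniform 4 Hz grid, linearly detrended, and Welch band powers are
integrated over the standard low-frequency (0.04-0.15 Hz) and
high-frequency (0.15-0.40 Hz) bands.

EDA and respiration get deliberately minimal treatments (phasic high-pass
plus threshold peak counting; zero-crossing cycle segmentation), matching
how coarsely those channels enter the group comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
REFRACTORY_S = 0.25
MIN_FREQ_SEGMENT_S = 60.0


@dataclass(frozen=True)
class NNSeries:
    """R-peak times and the normal-to-normal intervals between them."""

    peak_times_s: np.ndarray
    nn_ms: np.ndarray
    artifact_mask: np.ndarray     # True = flagged, excluded from metrics

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_times_s", np.asarray(self.peak_times_s, dtype=float))
        object.__setattr__(self, "nn_ms", np.asarray(self.nn_ms, dtype=float))
        object.__setattr__(self, "artifact_mask", np.asarray(self.artifact_mask, dtype=bool))
        if len(self.nn_ms) != max(len(self.peak_times_s) - 1, 0):
            raise ValueError("nn_ms length must be peaks - 1")
        if len(self.artifact_mask) != len(self.nn_ms):
            raise ValueError("artifact_mask length must match nn_ms")
        if (self.nn_ms <= 0).any():
            raise ValueError("NN intervals must be positive")

    @property
    def clean_nn_ms(self) -> np.ndarray:
        return self.nn_ms[~self.artifact_mask]

    @classmethod
    def from_peak_times(cls, peak_times_s) -> "NNSeries":
        pt = np.asarray(peak_times_s, dtype=float)
        nn = np.diff(pt) * 1000.0
        return cls(pt, nn, np.zeros(len(nn), dtype=bool))


@dataclass(frozen=True)
class HRVMetrics:
    """Per-segment HRV summary; NaN marks metrics that could not be computed."""

    segment: tuple
    mean_nn_ms: float
    sdnn_ms: float
    rmssd_ms: float
    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    n_intervals: int


@dataclass(frozen=True)
class PeripheralMetrics:
    segment: tuple
    scr_peak_count: int = 0
    scr_peak_amp_mean_uS: float = np.nan
    rsp_rate_mean_bpm: float = np.nan
    rsp_amp_mean: float = np.nan
    rsp_insp_s: float = np.nan
    rsp_exp_s: float = np.nan
    rsp_phase_ratio: float = np.nan


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def filter_ecg(raw: np.ndarray, fs: float, hp_cutoff_hz: float = 0.5,
               hp_order: int = 5, notch_hz: float = 50.0,
               notch_q: float = 30.0) -> np.ndarray:
    """Zero-phase high-pass (Butterworth, order 5, 0.5 Hz) + 50 Hz notch."""
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if fs <= 2 * notch_hz:
        raise ValueError(f"fs={fs} Hz cannot represent a {notch_hz} Hz notch")
    raw = np.asarray(raw, dtype=float)
    sos = sps.butter(hp_order, hp_cutoff_hz, btype="highpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, raw)
    b, a = sps.iirnotch(notch_hz, notch_q, fs=fs)
    return sps.filtfilt(b, a, out)


def detect_r_peaks(ecg: np.ndarray, fs: float, mad_factor: float = 4.0,
                   window_s: float = 10.0, amp_gate_frac: float = 0.5) -> NNSeries:
    """Gradient-steepness R-peak detector.

    Candidate QRS regions are runs where the absolute first difference of
    the (already filtered) signal exceeds a sliding median + ``mad_factor``
    * MAD threshold computed over ``window_s`` chunks; the R-peak is the
    sample of maximum amplitude within each region.  A sensitive gradient
    threshold deliberately over-generates candidates; spurious noise maxima
    are then pruned by an amplitude gate at ``amp_gate_frac`` of the upper
    (95th-percentile) candidate amplitude.  Peaks closer than the 250 ms
    refractory period keep the larger one.
    """
    ecg = np.asarray(ecg, dtype=float)
    grad = np.abs(np.diff(ecg))
    if len(grad) == 0 or grad.max() == 0:
        logger.warning("R-peak detection: flat signal, no peaks")
        return NNSeries.from_peak_times([])

    # piecewise (sliding-chunk) adaptive threshold on the gradient magnitude
    chunk = max(int(window_s * fs), 16)
    thresh = np.empty_like(grad)
    for start in range(0, len(grad), chunk):
        seg = grad[start:start + chunk]
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        thresh[start:start + chunk] = med + mad_factor * max(mad, 1e-12)
    above = grad > thresh

    if not above.any():
        logger.warning("R-peak detection found no candidate regions")
        return NNSeries.from_peak_times([])

    # contiguous candidate regions, dilated by a few samples to cover the apex
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > max(int(0.03 * fs), 2))
    region_bounds = zip(np.concatenate([[0], breaks + 1]),
                        np.concatenate([breaks, [len(idx) - 1]]))
    peaks = []
    pad = max(int(0.02 * fs), 2)
    for lo_i, hi_i in region_bounds:
        lo = max(idx[lo_i] - pad, 0)
        hi = min(idx[hi_i] + pad + 2, len(ecg))
        peaks.append(lo + int(np.argmax(ecg[lo:hi])))

    # amplitude gate against noise-driven candidate regions
    peaks = sorted(set(peaks))
    amps = ecg[np.asarray(peaks)]
    gate = amp_gate_frac * np.percentile(amps, 95)
    peaks = [p for p, a in zip(peaks, amps) if a >= gate]

    # refractory: keep the larger of peaks closer than 250 ms
    kept: list[int] = []
    for p in peaks:
        if kept and (p - kept[-1]) / fs < REFRACTORY_S:
            if ecg[p] > ecg[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    if not kept:
        logger.warning("R-peak detection found no peaks after refractory pruning")
    return NNSeries.from_peak_times(np.asarray(kept) / fs)


def clean_nn(nn: NNSeries, rel_tol: float = 0.2, median_window: int = 11) -> NNSeries:
    """Flag intervals deviating > rel_tol from an 11-point running median."""
    if len(nn.nn_ms) < 3:
        raise ValueError("need at least 3 NN intervals to clean")
    med = sps.medfilt(nn.nn_ms, kernel_size=min(median_window, len(nn.nn_ms) | 1))
    # medfilt zero-pads the edges; fall back to the global median there
    half = median_window // 2
    gmed = np.median(nn.nn_ms)
    med[:half] = gmed
    med[-half:] = gmed
    mask = np.abs(nn.nn_ms - med) > rel_tol * med
    if mask.mean() > 0.5:
        raise ValueError(f"{mask.mean():.0%} of intervals flagged as artifacts; segment unusable")
    return NNSeries(nn.peak_times_s, nn.nn_ms, mask | nn.artifact_mask)


# ---------------------------------------------------------------------------
# HRV metrics
# ---------------------------------------------------------------------------

def hrv_time(nn: NNSeries) -> tuple[float, float, float]:
    """(MeanNN, SDNN, RMSSD) in ms over the clean intervals.

    SDNN uses the sample (n-1) denominator.  Successive differences are
    taken between intervals that are adjacent in the original series and
    both clean.
    """
    x = nn.nn_ms
    ok = ~nn.artifact_mask
    clean = x[ok]
    if len(clean) < 3:
        logger.info("hrv_time: too few clean intervals (%d)", len(clean))
        return np.nan, np.nan, np.nan
    adj = ok[1:] & ok[:-1]
    diffs = (x[1:] - x[:-1])[adj]
    mean_nn = float(clean.mean())
    sdnn = float(clean.std(ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2))) if len(diffs) >= 2 else np.nan
    return mean_nn, sdnn, rmssd


def hrv_freq(nn: NNSeries, lf_band=LF_BAND, hf_band=HF_BAND,
             resample_hz: float = 4.0) -> tuple[float, float, float]:
    """(LF power, HF power, LF/HF) from a Welch PSD of the NN tachogram.

    The irregularly sampled tachogram (interval value at its ending peak
    time) is cubic-interpolated to ``resample_hz``, linearly detrended and
    fed to Welch with up-to-256 s segments.  Powers are trapezoidal band
    integrals in ms^2.
    """
    ok = ~nn.artifact_mask
    times = nn.peak_times_s[1:][ok]
    values = nn.nn_ms[ok]
    if len(values) < 4 or times[-1] - times[0] < MIN_FREQ_SEGMENT_S:
        logger.info("hrv_freq: segment too short for spectral metrics")
        return np.nan, np.nan, np.nan
    grid = np.arange(times[0], times[-1], 1.0 / resample_hz)
    tacho = CubicSpline(times, values)(grid)
    tacho = sps.detrend(tacho, type="linear")
    nperseg = min(len(tacho), int(256 * resample_hz))
    freqs, psd = sps.welch(tacho, fs=resample_hz, nperseg=nperseg)

    def band_power(band):
        lo, hi = band
        m = (freqs >= lo) & (freqs <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))

    lf = band_power(lf_band)
    hf = band_power(hf_band)
    ratio = lf / hf if hf > 0 else np.nan
    return lf, hf, ratio


def total_power(nn: NNSeries, resample_hz: float = 4.0,
                upper_hz: float = 2.0) -> float:
    """Welch PSD integral over [0, upper_hz]; bounds LF + HF from above."""
    ok = ~nn.artifact_mask
    times = nn.peak_times_s[1:][ok]
    values = nn.nn_ms[ok]
    grid = np.arange(times[0], times[-1], 1.0 / resample_hz)
    tacho = sps.detrend(CubicSpline(times, values)(grid), type="linear")
    nperseg = min(len(tacho), int(256 * resample_hz))
    freqs, psd = sps.welch(tacho, fs=resample_hz, nperseg=nperseg)
    m = freqs <= upper_hz
    return float(np.trapezoid(psd[m], freqs[m]))


def slice_nn(nn: NNSeries, t_start_s: float, t_end_s: float) -> NNSeries:
    """Sub-series of peaks falling inside [t_start_s, t_end_s)."""
    sel = (nn.peak_times_s >= t_start_s) & (nn.peak_times_s < t_end_s)
    pt = nn.peak_times_s[sel]
    if len(pt) < 2:
        return NNSeries.from_peak_times(pt)
    # carry over artifact flags of the intervals wholly inside the window
    first = int(np.flatnonzero(sel)[0])
    mask = nn.artifact_mask[first : first + len(pt) - 1]
    return NNSeries(pt, np.diff(pt) * 1000.0, mask)


def segment_hrv(nn: NNSeries, spans: pd.DataFrame,
                min_freq_span_s: float = MIN_FREQ_SEGMENT_S) -> list[HRVMetrics]:
    """HRV metrics per (block, level) time span plus per-block rows.

    ``spans`` needs columns block, level, t_start_s, t_end_s (wall-clock,
    from the participant's trial table).  Frequency metrics are computed
    only on spans of at least ``min_freq_span_s``; shorter spans report
    time-domain metrics with NaN spectral entries.
    """
    out: list[HRVMetrics] = []

    def one(segment, t0, t1):
        sub = slice_nn(nn, t0, t1)
        if len(sub.nn_ms) < 3:
            logger.info("segment %s: too few beats, metrics missing", segment)
            return HRVMetrics(segment, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, len(sub.nn_ms))
        mean_nn, sdnn, rmssd = hrv_time(sub)
        if t1 - t0 >= min_freq_span_s:
            lf, hf, ratio = hrv_freq(sub)
        else:
            lf = hf = ratio = np.nan
        return HRVMetrics(segment, mean_nn, sdnn, rmssd, lf, hf, ratio, len(sub.clean_nn_ms))

    for row in spans.itertuples(index=False):
        out.append(one((int(row.block), int(row.level)), row.t_start_s, row.t_end_s))
    for block, sub in spans.groupby("block"):
        out.append(one((int(block),), sub["t_start_s"].min(), sub["t_end_s"].max()))
    return out


# ---------------------------------------------------------------------------
# EDA / respiration
# ---------------------------------------------------------------------------

def scr_metrics(eda: np.ndarray, fs: float, window: tuple[float, float] | None = None,
                amp_threshold_uS: float = 0.05,
                phasic_cutoff_hz: float = 0.05) -> tuple[int, float]:
    """(peak count, mean peak rise amplitude) of skin-conductance responses.

    The phasic component is the 0.05 Hz high-passed trace; SCR peaks are
    local maxima whose rise from the preceding trough is at least
    ``amp_threshold_uS``.
    """
    if fs < 10:
        raise ValueError("fs must be >= 10 Hz")
    eda = np.asarray(eda, dtype=float)
    if window is not None:
        lo, hi = int(window[0] * fs), int(window[1] * fs)
        eda = eda[lo:hi]
    if len(eda) < int(2 * fs):
        return 0, np.nan
    sos = sps.butter(2, phasic_cutoff_hz, btype="highpass", fs=fs, output="sos")
    phasic = sps.sosfiltfilt(sos, eda)
    peaks, props = sps.find_peaks(phasic, prominence=amp_threshold_uS)
    if len(peaks) == 0:
        return 0, np.nan
    return int(len(peaks)), float(props["prominences"].mean())


def rsp_metrics(rsp: np.ndarray, fs: float,
                window: tuple[float, float] | None = None) -> PeripheralMetrics:
    """Respiration cycle statistics from zero-crossings of the detrended trace.

    Inspiration = trough-to-peak time, expiration = peak-to-trough; rate in
    cycles/min; amplitude = mean peak-trough excursion; phase ratio = mean
    inspiration / mean expiration.
    """
    if fs < 10:
        raise ValueError("fs must be >= 10 Hz")
    rsp = np.asarray(rsp, dtype=float)
    if window is not None:
        lo, hi = int(window[0] * fs), int(window[1] * fs)
        rsp = rsp[lo:hi]
    x = sps.detrend(rsp, type="linear")
    x = x - np.mean(x)
    crossings_up = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
    if len(crossings_up) < 3:
        return PeripheralMetrics(segment=("rsp",))
    peaks, troughs, amps, insp, exp_ = [], [], [], [], []
    for a, b in zip(crossings_up[:-1], crossings_up[1:]):
        seg = x[a:b]
        pk = a + int(np.argmax(seg))
        tr = a + int(np.argmin(seg))
        peaks.append(pk)
        troughs.append(tr)
        amps.append(x[pk] - x[tr])
        if tr > pk:                      # trough follows peak within the cycle
            exp_.append((tr - pk) / fs)
        if len(peaks) >= 2 and troughs[-2] < peaks[-1]:
            insp.append((peaks[-1] - troughs[-2]) / fs)
    n_cycles = len(crossings_up) - 1
    duration_min = (crossings_up[-1] - crossings_up[0]) / fs / 60.0
    rate = n_cycles / duration_min if duration_min > 0 else np.nan
    mean_insp = float(np.mean(insp)) if insp else np.nan
    mean_exp = float(np.mean(exp_)) if exp_ else np.nan
    ratio = mean_insp / mean_exp if exp_ and mean_exp > 0 and insp else np.nan
    return PeripheralMetrics(
        segment=("rsp",),
        rsp_rate_mean_bpm=float(rate),
        rsp_amp_mean=float(np.mean(amps)) if amps else np.nan,
        rsp_insp_s=mean_insp,
        rsp_exp_s=mean_exp,
        rsp_phase_ratio=ratio,
    )
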