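"""Cardiac interval analysis and normality-gated correlations.

Consumes inter-beat (P-P or R-R) interval series directly - beat detection
from raw ECG is out of scope. Provides per-period mean heart rate, the
LF/HF spectral ratio of heart-rate variability (0.04-0.15 Hz vs
0.15-0.40 Hz band power of a 4 Hz-resampled tachogram, Welch estimate),
robust outlier exclusion, and the Pearson-or-Spearman correlation whose
choice is gated on Shapiro-Wilk normality of both margins - mirroring the
stress-index analysis of the block-design study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal
from scipy import stats as sps

from .design import ExperimentDesign
from .stats import shapiro_wilk

__all__ = [
    "IntervalSeries",
    "HRVMetrics",
    "CorrelationResult",
    "mean_hr_per_period",
    "lf_hf",
    "detect_outliers",
    "correlate_gated",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class IntervalSeries:
    """Beat event times (s from record start) with derived intervals.

    Event times must be strictly increasing. ``plausible`` masks intervals
    inside the 0.3-2.0 s physiological band; metrics use only those.
    """

    event_times: np.ndarray
    interval_lo: float = 0.3
    interval_hi: float = 2.0

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        if t.ndim != 1 or t.shape[0] < 2:
            raise ValueError("need at least two beat events")
        if np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        """Successive inter-beat intervals, s (one fewer than events)."""
        return np.diff(self.event_times)

    @property
    def onsets(self) -> np.ndarray:
        """Onset time of each interval (the earlier beat of the pair)."""
        return self.event_times[:-1]

    @property
    def plausible(self) -> np.ndarray:
        iv = self.intervals
        return (iv >= self.interval_lo) & (iv <= self.interval_hi)

    @classmethod
    def from_intervals(
        cls, intervals: np.ndarray, start: float = 0.0, **kw
    ) -> "IntervalSeries":
        intervals = np.asarray(intervals, dtype=float)
        times = start + np.concatenate([[0.0], np.cumsum(intervals)])
        return cls(event_times=times, **kw)


@dataclass(frozen=True)
class HRVMetrics:
    lf_power: float
    hf_power: float

    @property
    def lf_hf(self) -> float:
        if self.hf_power <= 0:
            return float("nan")
        return self.lf_power / self.hf_power


def mean_hr_per_period(
    series: IntervalSeries, design: ExperimentDesign, min_beats: int = 5
) -> np.ndarray:
    """Mean instantaneous heart rate (60/interval, beats/min) in each of
    the 13 periods; an interval counts toward the window containing its
    onset. Windows with fewer than ``min_beats`` plausible beats are NaN.
    """
    onsets = series.onsets[series.plausible]
    hr = 60.0 / series.intervals[series.plausible]
    out = np.full(design.n_periods, np.nan)
    for p, (lo, hi) in enumerate(design.period_windows()):
        mask = (onsets >= lo) & (onsets < hi)
        if mask.sum() >= min_beats:
            out[p] = hr[mask].mean()
    return out


def lf_hf(
    series: IntervalSeries,
    window: tuple[float, float] | None = None,
    resample_hz: float = 4.0,
    segment_s: float = 120.0,
) -> HRVMetrics:
    """LF and HF band power of the interval tachogram in a time window.

    The plausible intervals inside the window are cubic-interpolated to a
    uniform ``resample_hz`` tachogram, linearly detrended, and the power
    spectral density estimated by Welch's averaged periodogram (segments
    of ``segment_s`` seconds, 50% overlap, capped at the record length).
    Band powers integrate the PSD over 0.04-0.15 and 0.15-0.40 Hz.
    Requires at least 60 s of beats for HF resolution.
    """
    onsets = series.onsets[series.plausible]
    intervals = series.intervals[series.plausible]
    if window is not None:
        lo, hi = window
        if hi - lo < 60.0 - 1e-9:
            raise ValueError(
                f"lf_hf window must span at least 60 s (HF resolution); "
                f"got {hi - lo:.1f} s"
            )
        m = (onsets >= lo) & (onsets < hi)
        onsets, intervals = onsets[m], intervals[m]
        min_span = 0.75 * (hi - lo)
    else:
        min_span = 60.0
    if onsets.size < 4 or onsets[-1] - onsets[0] < min_span:
        raise ValueError(
            "lf_hf: insufficient beats in the window "
            f"(span {0.0 if onsets.size == 0 else onsets[-1] - onsets[0]:.1f} s)"
        )
    t_uni = np.arange(onsets[0], onsets[-1], 1.0 / resample_hz)
    kind = "cubic" if onsets.size >= 4 else "linear"
    tach = interpolate.interp1d(onsets, intervals, kind=kind)(t_uni)
    tach = signal.detrend(tach, type="linear")
    nperseg = min(len(tach), int(segment_s * resample_hz))
    freqs, psd = signal.welch(
        tach, fs=resample_hz, nperseg=nperseg, noverlap=nperseg // 2
    )

    def band_power(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs < hi)
        if m.sum() < 2:
            m = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[m], freqs[m]))

    return HRVMetrics(
        lf_power=band_power(*LF_BAND), hf_power=band_power(*HF_BAND)
    )


def detect_outliers(values: np.ndarray, k: float = 3.5) -> np.ndarray:
    """Inclusion mask from the modified z-score (median/MAD) rule.

    Points with ``|value - median| > k * MAD / 0.6745`` are excluded
    (mask False); the 0.6745 factor makes the MAD a consistent estimate
    of the normal sigma, so k = 3.5 is the conventional modified-z cut.
    This documented stand-in approximates the unnamed commercial outlier
    screen of the original analysis chain. If the MAD is zero while the
    data still have spread, the Tukey interquartile fence (1.5 IQR) is
    used instead. NaNs are always excluded.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    v = values[finite]
    if v.size < 5:
        raise ValueError(f"outlier detection needs n >= 5 finite points, got {v.size}")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    keep = np.zeros_like(values, dtype=bool)
    if mad > 0:
        keep[finite] = np.abs(v - med) <= k * mad / 0.6745
    elif np.ptp(v) == 0:
        keep[finite] = True
    else:
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        keep[finite] = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
    return keep


@dataclass(frozen=True)
class CorrelationResult:
    method: str         # "pearson" or "spearman"
    coefficient: float
    n: int
    p: float


def p_from_correlation(r: float, n: int) -> float:
    """Two-tailed p via the t transform t = r sqrt(n-2) / sqrt(1-r^2)
    with n-2 df (applied identically to Pearson r and Spearman rho)."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation coefficient out of range: {r}")
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return 2.0 * float(sps.t.sf(abs(t), n - 2))


def correlate_gated(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> CorrelationResult:
    """Pearson correlation if both margins pass Shapiro-Wilk normality at
    ``alpha``, Spearman (midrank) otherwise; NaN pairs dropped first.

    The p-value uses the t transform with n-2 df for either coefficient,
    the convention of the source analysis chain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("correlate_gated needs two equal-length 1-D arrays")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    sx = shapiro_wilk(x)
    sy = shapiro_wilk(y)
    normal = (
        not sx.degenerate
        and not sy.degenerate
        and sx.p > alpha
        and sy.p > alpha
    )
    if normal:
        r = float(sps.pearsonr(x, y).statistic)
        method = "pearson"
    else:
        r = float(sps.spearmanr(x, y).statistic)
        method = "spearman"
    return CorrelationResult(method=method, coefficient=r, n=n, p=p_from_correlation(r, n))
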