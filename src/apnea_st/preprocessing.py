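"""Beat-level preprocessing: from raw ECG to fixed-size per-minute windows.

Pipeline, per recording:

1. R-peak detection with a Hamilton-style detector (8–16 Hz band-pass,
   differentiation, rectification, moving-window integration, adaptive
   threshold with a 200 ms refractory period), each detection refined to the
   local signal maximum within ±50 ms.
2. RR intervals and R-peak amplitudes extracted at the peak locations.
3. Artifact cleaning: RR values outside [0.4, 2.0] s or deviating more than
   20% from a 5-point running median are replaced by that running median
   (amplitudes by their own running median).
4. For each labeled minute with full ±2-minute context, both series are
   cubically interpolated onto 900 uniform points over the 5-min span,
   giving the two aligned model input channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .errors import ConfigError, SparseBeatsError
from .io_formats import ECGRecord, MinuteLabels

__all__ = [
    "BeatSeries",
    "SegmentWindow",
    "WindowSet",
    "detect_r_peaks",
    "extract_beat_series",
    "clean_rr",
    "resample_window",
    "build_windows",
    "preprocess_record",
    "fit_normalization",
    "apply_normalization",
]

WINDOW_S = 300.0       #: 5-min context window span
POINTS_PER_WINDOW = 900  #: samples per channel after cubic resampling (3 Hz effective)
CONTEXT_MINUTES = 2    #: labeled minute ± this many context minutes


@dataclass
class BeatSeries:
    """Detected beats for one recording.

    ``rr[i]`` is the interval ending at ``times[i+1]`` (successive
    differences), so ``len(rr) == len(times) - 1``.  After :func:`clean_rr`
    the RR values are a cleaned feature series and need no longer equal the
    exact time differences.
    """

    times: np.ndarray
    rr: np.ndarray
    amp: np.ndarray
    record_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.amp = np.asarray(self.amp, dtype=float)
        if self.times.size > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("beat times must be strictly increasing")
        expect = max(0, len(self.times) - 1)
        if len(self.rr) != expect:
            raise ValueError(f"rr length {len(self.rr)} != {expect} for {len(self.times)} beats")
        if len(self.amp) != len(self.times):
            raise ValueError("amp must align with times")
        if self.rr.size and not (self.rr > 0).all():
            raise ValueError("rr intervals must be positive")


@dataclass
class SegmentWindow:
    """One labeled minute's model input: aligned RR and amplitude channels."""

    record_id: str
    center_minute: int
    rr_channel: np.ndarray
    amp_channel: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.rr_channel = np.asarray(self.rr_channel, dtype=float)
        self.amp_channel = np.asarray(self.amp_channel, dtype=float)
        if len(self.rr_channel) != POINTS_PER_WINDOW or len(self.amp_channel) != POINTS_PER_WINDOW:
            raise ValueError(f"channels must have length {POINTS_PER_WINDOW}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------


def detect_r_peaks(
    ecg: ECGRecord,
    band_hz: tuple[float, float] = (8.0, 16.0),
    integrate_s: float = 0.08,
    refractory_s: float = 0.2,
    refine_s: float = 0.05,
    threshold_frac: float = 0.3125,
) -> np.ndarray:
    """Detect R-peak sample indices with a Hamilton-style adaptive detector.

    The detection function is the moving-average-integrated rectified
    derivative of the band-passed signal.  A candidate local maximum is
    accepted when it exceeds ``noise + threshold_frac * (signal - noise)``,
    where signal/noise levels are exponential running averages of accepted
    and rejected candidate heights; accepted detections are then snapped to
    the raw-signal maximum within ``±refine_s``.
    """
    x = ecg.signal
    if len(x) < ecg.fs:
        raise ValueError("need at least 1 s of signal")
    nyq = ecg.fs / 2.0
    sos = butter(3, [band_hz[0] / nyq, band_hz[1] / nyq], btype="band", output="sos")
    filt = sosfiltfilt(sos, x)
    detfun = np.abs(np.gradient(filt))
    win = max(1, int(round(integrate_s * ecg.fs)))
    detfun = np.convolve(detfun, np.ones(win) / win, mode="same")

    # candidate local maxima of the detection function
    cand = np.flatnonzero((detfun[1:-1] >= detfun[:-2]) & (detfun[1:-1] > detfun[2:])) + 1
    if cand.size == 0:
        return np.zeros(0, dtype=int)

    spk = float(np.percentile(detfun, 98))
    npk = float(np.percentile(detfun, 50))
    refractory = int(round(refractory_s * ecg.fs))
    refine = int(round(refine_s * ecg.fs))
    accepted: list[int] = []
    for c in cand:
        v = detfun[c]
        thr = npk + threshold_frac * (spk - npk)
        if v > thr:
            if accepted and c - accepted[-1] <= refractory:
                # ripple on the same QRS complex: keep the larger candidate
                if v > detfun[accepted[-1]]:
                    accepted[-1] = int(c)
                    spk = 0.875 * spk + 0.125 * v
                continue
            accepted.append(int(c))
            spk = 0.875 * spk + 0.125 * v
        else:
            npk = 0.875 * npk + 0.125 * v

    # snap to the local raw-signal maximum, then de-duplicate
    peaks: list[int] = []
    for c in accepted:
        lo, hi = max(0, c - refine), min(len(x), c + refine + 1)
        p = lo + int(np.argmax(x[lo:hi]))
        if peaks and p - peaks[-1] <= refractory:
            if x[p] > x[peaks[-1]]:
                peaks[-1] = p
            continue
        peaks.append(p)
    return np.asarray(peaks, dtype=int)


def extract_beat_series(ecg: ECGRecord, peaks: np.ndarray) -> BeatSeries:
    """Turn peak indices into beat times (s), RR intervals and amplitudes (mV)."""
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size > 1 and not (np.diff(peaks) > 0).all():
        raise ValueError("peaks must be strictly ascending")
    if peaks.size and (peaks.min() < 0 or peaks.max() >= len(ecg.signal)):
        raise ValueError("peak indices outside signal bounds")
    times = peaks / ecg.fs + ecg.start_time
    return BeatSeries(
        times=times,
        rr=np.diff(times),
        amp=ecg.signal[peaks],
        record_id=ecg.record_id,
    )


# ---------------------------------------------------------------------------
# RR artifact cleaning
# ---------------------------------------------------------------------------


def running_median(x: np.ndarray, k: int) -> np.ndarray:
    """Centered running median of window ``k`` with edge-replicated padding."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    h = k // 2
    xp = np.concatenate([np.full(h, x[0]), x, np.full(h, x[-1])])
    windows = np.lib.stride_tricks.sliding_window_view(xp, k)
    return np.median(windows, axis=1)


def clean_rr(
    series: BeatSeries,
    lo_s: float = 0.4,
    hi_s: float = 2.0,
    dev_frac: float = 0.2,
    median_k: int = 5,
    clean_amp: bool = True,
) -> BeatSeries:
    """Replace physiologically unexplained RR values by a running median.

    An RR value is flagged when outside ``[lo_s, hi_s]`` or deviating from
    the ``median_k``-point running median by more than ``dev_frac`` of that
    median.  Flagged RR values are replaced by the running median; the
    amplitude of the beat ending the flagged interval is replaced by the
    amplitude series' own running median (disable with ``clean_amp=False``).
    """
    if lo_s >= hi_s:
        raise ConfigError(f"lo_s ({lo_s}) must be < hi_s ({hi_s})")
    if median_k < 3 or median_k % 2 == 0:
        raise ConfigError("median_k must be odd and >= 3")
    if series.rr.size == 0:
        return BeatSeries(series.times.copy(), series.rr.copy(), series.amp.copy(), series.record_id)
    med = running_median(series.rr, median_k)
    flagged = (series.rr < lo_s) | (series.rr > hi_s) | (np.abs(series.rr - med) > dev_frac * med)
    rr = np.where(flagged, med, series.rr)
    amp = series.amp.copy()
    if clean_amp and flagged.any():
        amp_med = running_median(series.amp, median_k)
        amp_idx = np.flatnonzero(flagged) + 1  # rr[i] ends at beat i+1
        amp[amp_idx] = amp_med[amp_idx]
    return BeatSeries(series.times.copy(), rr, amp, series.record_id)


# ---------------------------------------------------------------------------
# Windowing and cubic resampling
# ---------------------------------------------------------------------------


def resample_window(
    series: BeatSeries,
    t0: float,
    t1: float,
    n: int = POINTS_PER_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-interpolate RR and amplitude onto ``n`` uniform points over [t0, t1).

    RR knots sit at the time of the beat ending each interval; amplitude
    knots at every beat time.  Evaluation points outside the in-window knot
    range take the nearest knot's value.  Raises :class:`SparseBeatsError`
    when fewer than 4 in-window knots exist for either channel.
    """
    grid = t0 + (t1 - t0) * np.arange(n) / n
    rr_t = series.times[1:]
    rr_in = (rr_t >= t0) & (rr_t <= t1)
    amp_in = (series.times >= t0) & (series.times <= t1)
    if rr_in.sum() < 4 or amp_in.sum() < 4:
        raise SparseBeatsError(
            f"window [{t0:g}, {t1:g}) s holds {int(amp_in.sum())} beats; need >= 4"
        )

    def interp(knot_t: np.ndarray, knot_v: np.ndarray) -> np.ndarray:
        spline = CubicSpline(knot_t, knot_v)
        return spline(np.clip(grid, knot_t[0], knot_t[-1]))

    return (
        interp(rr_t[rr_in], series.rr[rr_in]),
        interp(series.times[amp_in], series.amp[amp_in]),
    )


def build_windows(
    series: BeatSeries,
    labels: MinuteLabels,
    n_points: int = POINTS_PER_WINDOW,
    context: int = CONTEXT_MINUTES,
) -> list[SegmentWindow]:
    """One window per labeled minute with full ±context; sparse windows dropped."""
    out: list[SegmentWindow] = []
    m_total = len(labels)
    for m in range(context, m_total - context):
        t0 = 60.0 * (m - context)
        try:
            rr_ch, amp_ch = resample_window(series, t0, t0 + WINDOW_S, n=n_points)
        except SparseBeatsError:
            continue
        out.append(
            SegmentWindow(
                record_id=labels.record_id,
                center_minute=m,
                rr_channel=rr_ch,
                amp_channel=amp_ch,
                label=int(labels.labels[m]),
            )
        )
    return out


def preprocess_record(ecg: ECGRecord, labels: MinuteLabels, **clean_kwargs) -> list[SegmentWindow]:
    """Full per-record pipeline: detect, extract, clean, window."""
    peaks = detect_r_peaks(ecg)
    series = extract_beat_series(ecg, peaks)
    series = clean_rr(series, **clean_kwargs)
    return build_windows(series, labels)


# ---------------------------------------------------------------------------
# Window container with persistence and normalization
# ---------------------------------------------------------------------------


@dataclass
class WindowSet:
    """A batch of segment windows as arrays: ``X`` is (n, 900, 2) [RR, amplitude]."""

    X: np.ndarray
    y: np.ndarray
    record_ids: list[str] = field(default_factory=list)
    center_minutes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.center_minutes = np.asarray(self.center_minutes, dtype=int)
        if self.X.ndim != 3 or self.X.shape[2] != 2:
            raise ValueError(f"X must be (n, {POINTS_PER_WINDOW}, 2), got {self.X.shape}")
        if len(self.y) != len(self.X):
            raise ValueError("y must align with X")

    def __len__(self) -> int:
        return len(self.X)

    @classmethod
    def from_windows(cls, windows: list[SegmentWindow]) -> "WindowSet":
        if not windows:
            return cls(X=np.zeros((0, POINTS_PER_WINDOW, 2)), y=np.zeros(0, dtype=int))
        X = np.stack([np.stack([w.rr_channel, w.amp_channel], axis=-1) for w in windows])
        return cls(
            X=X,
            y=np.array([w.label for w in windows], dtype=int),
            record_ids=[w.record_id for w in windows],
            center_minutes=np.array([w.center_minute for w in windows], dtype=int),
        )

    def subset(self, idx: np.ndarray) -> "WindowSet":
        idx = np.asarray(idx)
        return WindowSet(
            X=self.X[idx],
            y=self.y[idx],
            record_ids=[self.record_ids[i] for i in idx] if self.record_ids else [],
            center_minutes=self.center_minutes[idx] if self.center_minutes.size else self.center_minutes,
            norm_mean=self.norm_mean,
            norm_sd=self.norm_sd,
        )

    def save(self, path: str | Path) -> None:
        """Persist as ``<path>.npz`` plus a JSON sidecar ``<path>.json``."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), X=self.X, y=self.y,
                            center_minutes=self.center_minutes)
        sidecar = {
            "record_ids": self.record_ids,
            "norm_mean": None if self.norm_mean is None else list(self.norm_mean),
            "norm_sd": None if self.norm_sd is None else list(self.norm_sd),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "WindowSet":
        path = Path(path)
        arrs = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            X=arrs["X"],
            y=arrs["y"],
            record_ids=sidecar["record_ids"],
            center_minutes=arrs["center_minutes"],
            norm_mean=None if sidecar["norm_mean"] is None else np.asarray(sidecar["norm_mean"]),
            norm_sd=None if sidecar["norm_sd"] is None else np.asarray(sidecar["norm_sd"]),
        )


def fit_normalization(ws: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and SD over all windows (for the training set)."""
    mean = ws.X.reshape(-1, 2).mean(axis=0)
    sd = ws.X.reshape(-1, 2).std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def apply_normalization(ws: WindowSet, mean: np.ndarray, sd: np.ndarray) -> WindowSet:
    """Z-score each channel with stored training constants."""
    return WindowSet(
        X=(ws.X - mean) / sd,
        y=ws.y,
        record_ids=list(ws.record_ids),
        center_minutes=ws.center_minutes.copy(),
        norm_mean=np.asarray(mean, dtype=float),
        norm_sd=np.asarray(sd, dtype=float),
    )
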