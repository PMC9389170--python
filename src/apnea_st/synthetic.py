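"""Synthetic single-lead ECG with known beats and planted apnea episodes.

The generator is the package's download-free test bed.  It emulates the one
physiological signature the classifier's features can see: during apnea the
heart rate swings cyclically (the bradycardia–tachycardia pattern), so RR
intervals oscillate around the baseline with a configurable period and
fractional depth, and R-peak amplitudes are modulated the same way.  Outside
apnea, RR intervals are i.i.d. Gaussian around the baseline.  Beats are
rendered as a Ricker (Mexican-hat) pulse — a biphasic QRS-like template
about 100 ms wide whose sampled maximum sits exactly at the beat's sample.

It is deliberately not a physiological simulator: no P/T waves, respiration,
arrhythmias or electrode artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io_formats import (
    ECGRecord,
    MinuteLabels,
    RespEvent,
    ucddb_minute_labels,
    write_apnea_minute_labels,
    write_wfdb_record,
)

__all__ = ["SimConfig", "GroundTruth", "generate_beats", "synthesize_ecg", "generate_dataset"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic recording.

    RR intervals outside apnea are ``Normal(base_rr_mean, base_rr_sd)``;
    inside an apnea interval the mean is modulated by
    ``1 + apnea_rr_depth * sin(2*pi*t/apnea_cycle_s)`` and amplitudes by the
    analogous factor with ``apnea_amp_depth``.
    """

    fs: float = 100.0
    duration_s: float = 1800.0
    base_rr_mean: float = 0.85
    base_rr_sd: float = 0.02
    apnea_intervals: tuple[tuple[float, float], ...] = ()
    apnea_cycle_s: float = 40.0
    apnea_rr_depth: float = 0.25
    apnea_amp_depth: float = 0.3
    amp_base_mv: float = 1.0
    amp_jitter_sd: float = 0.01
    noise_sd: float = 0.0
    seed: int = 0

    # hard physiological bounds every generated RR must respect
    rr_lo: float = 0.3
    rr_hi: float = 2.5

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigError("fs and duration_s must be positive")
        worst_lo = self.base_rr_mean * (1 - self.apnea_rr_depth) - 5 * self.base_rr_sd
        worst_hi = self.base_rr_mean * (1 + self.apnea_rr_depth) + 5 * self.base_rr_sd
        if not (self.rr_lo < worst_lo and worst_hi < self.rr_hi):
            raise ConfigError(
                f"RR parameters can leave ({self.rr_lo}, {self.rr_hi}) s: "
                f"range [{worst_lo:.3f}, {worst_hi:.3f}]"
            )
        iv = sorted(self.apnea_intervals)
        for (a0, a1) in iv:
            if not (0 <= a0 < a1 <= self.duration_s):
                raise ConfigError(f"apnea interval ({a0}, {a1}) outside [0, {self.duration_s}]")
        for (_, a1), (b0, _) in zip(iv, iv[1:]):
            if b0 < a1:
                raise ConfigError("apnea intervals must not overlap")

    @property
    def n_minutes(self) -> int:
        return int(self.duration_s // 60)


@dataclass
class GroundTruth:
    """Planted truth for one recording: beat times/amplitudes and minute labels."""

    beat_times: np.ndarray
    beat_amplitudes: np.ndarray
    minute_labels: MinuteLabels

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.beat_amplitudes = np.asarray(self.beat_amplitudes, dtype=float)
        if self.beat_times.size > 1 and not (np.diff(self.beat_times) > 0).all():
            raise ValueError("beat_times must be strictly increasing")


def _in_apnea(t: float, intervals: Sequence[tuple[float, float]]) -> bool:
    return any(a0 <= t < a1 for a0, a1 in intervals)


def generate_beats(cfg: SimConfig) -> GroundTruth:
    """Draw beat times and amplitudes under the configured apnea episodes.

    Minute labels are derived from ``cfg.apnea_intervals`` with the same
    strictly-more-than-5-s occupancy rule used for scored respiratory events,
    so generator output is consistent with the event-based labeler.
    """
    rng = np.random.default_rng(cfg.seed)
    times, amps = [], []
    t = float(rng.normal(cfg.base_rr_mean, cfg.base_rr_sd))
    while t < cfg.duration_s:
        if _in_apnea(t, cfg.apnea_intervals):
            phase = np.sin(2 * np.pi * t / cfg.apnea_cycle_s)
            rr_mean = cfg.base_rr_mean * (1 + cfg.apnea_rr_depth * phase)
            amp = cfg.amp_base_mv * (1 + cfg.apnea_amp_depth * phase)
        else:
            rr_mean = cfg.base_rr_mean
            amp = cfg.amp_base_mv
        times.append(t)
        amps.append(amp + rng.normal(0.0, cfg.amp_jitter_sd))
        rr = rr_mean + rng.normal(0.0, cfg.base_rr_sd)
        t += float(np.clip(rr, cfg.rr_lo + 0.05, cfg.rr_hi - 0.05))
    events = [RespEvent(a0, a1 - a0, "APNEA") for a0, a1 in cfg.apnea_intervals]
    labels = ucddb_minute_labels(events, cfg.n_minutes, record_id=f"sim{cfg.seed}")
    return GroundTruth(
        beat_times=np.asarray(times),
        beat_amplitudes=np.asarray(amps),
        minute_labels=labels,
    )


def _qrs_template(fs: float, sigma_s: float = 0.02, half_width_s: float = 0.05) -> np.ndarray:
    """Ricker wavelet sampled at fs; unit peak at the center sample."""
    k = int(round(half_width_s * fs))
    t = np.arange(-k, k + 1) / fs
    u = (t / sigma_s) ** 2
    return (1.0 - u) * np.exp(-u / 2.0)


def synthesize_ecg(truth: GroundTruth, cfg: SimConfig) -> ECGRecord:
    """Render beats as amplitude-scaled QRS templates plus Gaussian noise."""
    n = int(round(cfg.duration_s * cfg.fs))
    template = _qrs_template(cfg.fs)
    half = len(template) // 2
    if truth.beat_times.size > 1:
        min_rr = float(np.min(np.diff(truth.beat_times)))
        if len(template) / cfg.fs > min_rr:
            raise ConfigError(
                f"QRS template ({len(template) / cfg.fs:.3f} s) wider than shortest RR ({min_rr:.3f} s)"
            )
    if truth.beat_times.size and truth.beat_times.max() >= cfg.duration_s:
        raise ConfigError("beat times must lie within the record duration")
    signal = np.zeros(n)
    for bt, amp in zip(truth.beat_times, truth.beat_amplitudes):
        c = int(round(bt * cfg.fs))
        lo, hi = c - half, c + half + 1
        tlo, thi = max(0, lo), min(n, hi)
        signal[tlo:thi] += amp * template[tlo - lo : len(template) - (hi - thi)]
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed + 1_000_003)
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=n)
    return ECGRecord(record_id=f"sim{cfg.seed}", fs=cfg.fs, signal=signal)


def _draw_apnea_intervals(
    rng: np.random.Generator,
    duration_s: float,
    prevalence: float,
    episode_s: tuple[float, float] = (120.0, 300.0),
) -> tuple[tuple[float, float], ...]:
    """Alternate normal gaps and apnea episodes targeting the given SA-minute fraction.

    An episode of length E seconds marks about E/60 + 1 minutes under the
    >5 s occupancy rule (both boundary minutes usually qualify), so the gap
    is sized from E + 60 rather than E to hit the prevalence on labels.
    """
    if prevalence <= 0:
        return ()
    intervals = []
    t = float(rng.uniform(30.0, 120.0))
    while t < duration_s - 60.0:
        ep = float(rng.uniform(*episode_s))
        end = min(t + ep, duration_s)
        intervals.append((t, end))
        gap = (ep + 60.0) / prevalence - ep
        t = end + float(gap * rng.uniform(0.7, 1.3))
    return tuple(intervals)


def generate_dataset(
    n_records: int,
    out_dir: str | Path,
    seed: int = 0,
    duration_s: float = 1800.0,
    prevalence: float = 0.3,
    noise_sd: float = 0.0,
    fs: float = 100.0,
) -> dict:
    """Write ``n_records`` WFDB-compatible records with annotations and a manifest.

    Per-record seeds are derived from the master seed through a
    ``SeedSequence`` spawn, so each record is independently reproducible and
    the manifest is byte-identical across runs with the same master seed.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(seed).spawn(n_records)
    manifest = {"master_seed": seed, "records": []}
    for i, child in enumerate(children):
        rec_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(rec_seed)
        intervals = _draw_apnea_intervals(rng, duration_s, prevalence)
        cfg = SimConfig(
            fs=fs,
            duration_s=duration_s,
            apnea_intervals=intervals,
            noise_sd=noise_sd,
            seed=rec_seed,
        )
        truth = generate_beats(cfg)
        ecg = synthesize_ecg(truth, cfg)
        record_id = f"sim{i:02d}"
        write_wfdb_record(out_dir, record_id, fs, ecg.signal)
        truth.minute_labels.record_id = record_id
        write_apnea_minute_labels(out_dir / f"{record_id}.ann", truth.minute_labels)
        manifest["records"].append(
            {
                "record_id": record_id,
                "seed": rec_seed,
                "fs": fs,
                "duration_s": duration_s,
                "apnea_intervals": [[round(a, 6), round(b, 6)] for a, b in intervals],
                "beat_times": [round(float(v), 6) for v in truth.beat_times],
                "beat_amplitudes": [round(float(v), 6) for v in truth.beat_amplitudes],
                "minute_labels": [int(v) for v in truth.minute_labels.labels],
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
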