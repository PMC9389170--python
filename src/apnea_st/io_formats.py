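"""Readers and writers for the physiological formats the pipeline touches.

Single-lead ECG arrives either as WFDB records (.hea header + 16-bit .dat
signal, the layout used by the PhysioNet Apnea-ECG benchmark) or as EDF
polysomnograms (the UCDDB layout).  Per-minute ground truth comes from a
plain-text apnea annotation stream (one A/N mark per minute) or is derived
from scored respiratory events via the >5 s occupancy rule.

Only the subset of each format the pipeline needs is supported: WFDB format
16 with a shared .dat file, and EDF with 2-byte samples.  All signals are
normalized to millivolts at read time.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError

__all__ = [
    "ECGRecord",
    "MinuteLabels",
    "RespEvent",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_apnea_minute_labels",
    "write_apnea_minute_labels",
    "read_edf_channel",
    "write_edf",
    "read_resp_events",
    "ucddb_minute_labels",
    "write_minute_labels_csv",
    "DEFAULT_UCDDB_EXCLUDED",
    "DEFAULT_SA_EVENT_TYPES",
]

#: UCDDB subjects without scored apnea events, excluded from analyses by
#: configuration rather than reader logic.
DEFAULT_UCDDB_EXCLUDED = ("ucddb008", "ucddb011", "ucddb013", "ucddb018")

#: Respiratory event types counted as sleep-apnea events when deriving
#: per-minute labels.  ``None`` entries in user configs mean "all types".
DEFAULT_SA_EVENT_TYPES = frozenset(
    {
        "APNEA-O",
        "APNEA-C",
        "APNEA-M",
        "HYP-O",
        "HYP-C",
        "HYP-M",
        "APNEA",
        "HYPOPNEA",
    }
)


@dataclass
class ECGRecord:
    """One continuous single-lead ECG trace.

    Attributes
    ----------
    record_id : str
        Identifier, typically the file stem.
    fs : float
        Sampling rate in Hz.
    signal : numpy.ndarray
        Voltage samples in mV.
    start_time : float
        Offset of the first sample in seconds (default 0).
    """

    record_id: str
    fs: float
    signal: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 1 or self.signal.size < 1:
            raise ValueError("signal must be a non-empty 1-D array")

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs


@dataclass
class MinuteLabels:
    """Binary per-minute sleep-apnea labels (0 = normal, 1 = SA)."""

    record_id: str
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must contain only 0/1")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class RespEvent:
    """A scored respiratory event: onset and duration in seconds from record start."""

    onset_s: float
    duration_s: float
    event_type: str = ""

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"event duration must be > 0, got {self.duration_s}")


# ---------------------------------------------------------------------------
# WFDB (format 16)
# ---------------------------------------------------------------------------


def _parse_header(hea_path: Path):
    try:
        lines = [
            ln.strip()
            for ln in hea_path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    except OSError as exc:
        raise FormatError(f"cannot read WFDB header {hea_path}: {exc}") from exc
    if not lines:
        raise FormatError(f"empty WFDB header {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed WFDB record line in {hea_path}: {lines[0]!r}")
    record_id, n_sig = head[0], int(head[1])
    fs = float(head[2])
    n_samples = int(head[3])
    if len(lines) - 1 < n_sig:
        raise FormatError(f"{hea_path} declares {n_sig} signals but lists {len(lines) - 1}")
    sigs = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1]
        if fmt != "16":
            raise FormatError(f"unsupported WFDB signal format {fmt!r} in {hea_path}")
        gain, baseline, units = 200.0, 0.0, "mV"
        if len(tok) > 2:
            g = tok[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(", 1)
                baseline = float(b)
            gain = float(g)
        sigs.append({"file": fname, "gain": gain, "baseline": baseline, "units": units})
    return record_id, fs, n_samples, sigs


def read_wfdb_record(path: str | Path, channel: int = 0) -> ECGRecord:
    """Read one channel of a WFDB format-16 record in physical units (mV).

    Parameters
    ----------
    path : path to the record, with or without the ``.hea`` suffix.
    channel : zero-based signal index within the record.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"WFDB header not found: {hea}")
    record_id, fs, n_samples, sigs = _parse_header(hea)
    if not 0 <= channel < len(sigs):
        raise IndexError(f"channel {channel} out of range for record with {len(sigs)} signals")
    # all signals share one interleaved .dat in this subset of the format
    dat = hea.parent / sigs[channel]["file"]
    if not dat.exists():
        raise FormatError(f"WFDB signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    n_sig = len(sigs)
    if raw.size != n_samples * n_sig:
        raise FormatError(
            f"{dat} holds {raw.size} samples, expected {n_samples * n_sig} "
            f"({n_samples} frames x {n_sig} signals)"
        )
    adu = raw.reshape(n_samples, n_sig)[:, channel].astype(float)
    spec = sigs[channel]
    physical = (adu - spec["baseline"]) / spec["gain"]
    if spec["units"].lower() in ("uv", "µv"):
        physical = physical / 1000.0
    elif spec["units"].lower() == "v":
        physical = physical * 1000.0
    return ECGRecord(record_id=record_id, fs=fs, signal=physical)


def write_wfdb_record(
    out_dir: str | Path,
    record_id: str,
    fs: float,
    signals: np.ndarray,
    units: str = "mV",
    gain: float = 200.0,
) -> Path:
    """Write signals as a WFDB format-16 record (.hea + .dat); returns the header path.

    ``signals`` is (n_samples,) or (n_samples, n_sig); values are physical mV,
    quantized at ``gain`` ADC units per mV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig = np.atleast_2d(np.asarray(signals, dtype=float))
    if sig.shape[0] == 1 and np.asarray(signals).ndim == 1:
        sig = sig.T
    n_samples, n_sig = sig.shape
    adu = np.clip(np.round(sig * gain), -32768, 32767).astype("<i2")
    (out_dir / f"{record_id}.dat").write_bytes(adu.reshape(-1).tobytes())
    lines = [f"{record_id} {n_sig} {fs:g} {n_samples}"]
    for _ in range(n_sig):
        lines.append(f"{record_id}.dat 16 {gain:g}(0)/{units} 16 0 0 0 0 ECG")
    hea = out_dir / f"{record_id}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


# ---------------------------------------------------------------------------
# Per-minute apnea annotations (text stream of A/N marks)
# ---------------------------------------------------------------------------

_MARK_TO_LABEL = {"A": 1, "N": 0}


def read_apnea_minute_labels(path: str | Path) -> MinuteLabels:
    """Read a per-minute apnea annotation stream: one ``A`` (apnea) or ``N`` mark per minute."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file not found: {path}")
    labels = []
    for i, line in enumerate(path.read_text().split()):
        mark = line.strip()
        if mark not in _MARK_TO_LABEL:
            raise FormatError(f"unknown annotation mark {mark!r} at position {i} in {path}")
        labels.append(_MARK_TO_LABEL[mark])
    return MinuteLabels(record_id=path.stem, labels=np.asarray(labels, dtype=int))


def write_apnea_minute_labels(path: str | Path, labels: MinuteLabels) -> None:
    marks = "".join("A\n" if v else "N\n" for v in labels.labels)
    Path(path).write_text(marks)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def read_edf_channel(path: str | Path, channel_name: str) -> ECGRecord:
    """Read one named channel from an EDF file, rescaled to mV.

    Raises
    ------
    KeyError
        If the channel is absent; the message lists the channels present.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    if channel_name not in raw.ch_names:
        raise KeyError(
            f"channel {channel_name!r} not in {path.name}; available: {raw.ch_names}"
        )
    raw = raw.pick([channel_name]).load_data(verbose="error")
    data = raw.get_data()[0] * 1000.0  # mne returns SI volts
    return ECGRecord(record_id=path.stem, fs=float(raw.info["sfreq"]), signal=data)


def write_edf(
    path: str | Path,
    channels: Sequence[np.ndarray],
    fs: Sequence[float],
    labels: Sequence[str],
    units: str = "mV",
    record_dur_s: float = 1.0,
) -> Path:
    """Write a minimal EDF file (2-byte samples, one data-record block per second).

    Intended for synthetic fixtures; physical values are quantized into the
    16-bit digital range spanning each channel's [floor(min)-1, ceil(max)+1].
    """
    path = Path(path)
    channels = [np.asarray(c, dtype=float) for c in channels]
    ns = len(channels)
    if not (ns == len(fs) == len(labels)):
        raise ValueError("channels, fs and labels must have equal length")
    n_records = int(np.ceil(max(len(c) / f for c, f in zip(channels, fs)) / record_dur_s))

    def f(vals, w):
        out = b""
        for v in vals:
            s = str(v).encode()
            if len(s) > w:
                raise ValueError(f"EDF header field too long: {v!r}")
            out += s.ljust(w)
        return out

    pmin = [float(np.floor(c.min())) - 1 for c in channels]
    pmax = [float(np.ceil(c.max())) + 1 for c in channels]
    spr = [int(round(f_ * record_dur_s)) for f_ in fs]
    hdr = b"0".ljust(8)
    hdr += b"".ljust(80) + b"".ljust(80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += f([256 * (ns + 1)], 8) + b"".ljust(44)
    hdr += f([n_records], 8) + f([f"{record_dur_s:g}"], 8) + f([ns], 4)
    hdr += f(labels, 16) + f([""] * ns, 80) + f([units] * ns, 8)
    hdr += f([f"{v:g}" for v in pmin], 8) + f([f"{v:g}" for v in pmax], 8)
    hdr += f([-32768] * ns, 8) + f([32767] * ns, 8) + f([""] * ns, 80)
    hdr += f(spr, 8) + f([""] * ns, 32)
    body = bytearray()
    digital = [
        np.round((c - lo) / (hi - lo) * 65535.0 - 32768.0).astype("<i2")
        for c, lo, hi in zip(channels, pmin, pmax)
    ]
    for r in range(n_records):
        for d, n in zip(digital, spr):
            seg = d[r * n : (r + 1) * n]
            if len(seg) < n:
                seg = np.concatenate([seg, np.zeros(n - len(seg), "<i2")])
            body += seg.tobytes()
    path.write_bytes(hdr + bytes(body))
    return path


# ---------------------------------------------------------------------------
# Respiratory events and the >5 s per-minute labeling rule
# ---------------------------------------------------------------------------


def read_resp_events(path: str | Path) -> list[RespEvent]:
    """Read a tab/comma-separated respiratory event table (onset_s, duration_s, type)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"event table not found: {path}")
    events = []
    with path.open(newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample else ","
        reader = csv.reader(fh, delimiter=delim)
        for row in reader:
            if not row or row[0].strip().lower() in ("onset", "onset_s", "time"):
                continue
            try:
                onset, dur = float(row[0]), float(row[1])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"malformed event row {row!r} in {path}") from exc
            etype = row[2].strip() if len(row) > 2 else ""
            events.append(RespEvent(onset_s=onset, duration_s=dur, event_type=etype))
    return events


def ucddb_minute_labels(
    events: Sequence[RespEvent],
    n_minutes: int,
    record_id: str = "",
    sa_event_types: frozenset[str] | None = None,
    threshold_s: float = 5.0,
) -> MinuteLabels:
    """Label minute ``m`` as SA iff apnea events occupy strictly more than
    ``threshold_s`` seconds of [60m, 60(m+1)).

    Occupancy is the measure of the union of qualifying events (overlapping
    events do not double-count).  ``sa_event_types=None`` counts every event;
    otherwise only events whose type (case-insensitive) is in the set.
    """
    if n_minutes < 0:
        raise ValueError(f"n_minutes must be >= 0, got {n_minutes}")
    if sa_event_types is not None:
        sa_event_types = frozenset(t.upper() for t in sa_event_types)
    spans = sorted(
        (ev.onset_s, ev.onset_s + ev.duration_s)
        for ev in events
        if sa_event_types is None or ev.event_type.upper() in sa_event_types
    )
    merged: list[list[float]] = []
    for start, stop in spans:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])
    occupancy = np.zeros(n_minutes, dtype=float)
    for start, stop in merged:
        m_lo = max(0, int(np.floor(start / 60.0)))
        m_hi = min(n_minutes, int(np.ceil(stop / 60.0)))
        for m in range(m_lo, m_hi):
            occupancy[m] += max(0.0, min(stop, 60.0 * (m + 1)) - max(start, 60.0 * m))
    labels = (occupancy > threshold_s).astype(int)
    return MinuteLabels(record_id=record_id, labels=labels)


def write_minute_labels_csv(path: str | Path, labels: MinuteLabels) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "minute", "label"])
        for m, v in enumerate(labels.labels):
            w.writerow([labels.record_id, m, int(v)])
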