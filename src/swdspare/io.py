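"""EEG recordings, discharge annotations, and preictal/ictal windowing.

The on-disk interchange formats are EDF for the signals (read through MNE,
written by :mod:`swdspare.edf`) and a flat CSV for spike-wave discharge (SWD)
annotations with columns ``patient_id, swd_id, onset_s, offset_s, label``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import CANONICAL_16, normalize_label

LABEL_SPARED = 0
LABEL_IMPAIRED = 1

ANNOTATION_COLUMNS = ["patient_id", "swd_id", "onset_s", "offset_s", "label"]


class EegIoError(ValueError):
    """Malformed input file or annotation."""


class WindowExtractionError(ValueError):
    """Event cannot supply a full preictal/ictal window pair."""


class Reference(str, enum.Enum):
    original = "original"
    Cz = "Cz"
    common_average = "common_average"


@dataclass
class Recording:
    """Multichannel EEG segment: ``samples`` is channels x time in µV."""

    samples: np.ndarray
    rate_hz: float
    channel_names: list[str]
    patient_id: str
    reference: Reference = Reference.original

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise EegIoError("samples must be 2-D (channels x time)")
        if self.rate_hz <= 0:
            raise EegIoError("rate_hz must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise EegIoError("channel_names length must match channel count")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise EegIoError("channel_names must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass(frozen=True)
class SwdEvent:
    """One annotated spike-wave discharge.

    ``label`` is 0 (behaviorally spared), 1 (impaired) or None (unlabeled).
    """

    patient_id: str
    swd_id: str
    onset_s: float
    offset_s: float
    label: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.offset_s):
            raise EegIoError(
                f"event {self.swd_id}: need 0 <= onset < offset, "
                f"got [{self.onset_s}, {self.offset_s}]"
            )
        if self.label is not None and self.label not in (LABEL_SPARED, LABEL_IMPAIRED):
            raise EegIoError(f"event {self.swd_id}: label must be 0, 1 or None")

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1000.0


@dataclass(frozen=True)
class WindowConfig:
    """Preictal/ictal analysis window lengths in milliseconds.

    Defaults are the lengths found optimal for spatial-pattern features:
    1000 ms before onset and 500 ms after.
    """

    pre_ms: float = 1000.0
    ict_ms: float = 500.0

    def __post_init__(self) -> None:
        if not (100 <= self.pre_ms <= 5000):
            raise EegIoError("pre_ms must lie in [100, 5000]")
        if not (100 <= self.ict_ms <= 1000):
            raise EegIoError("ict_ms must lie in [100, 1000]")

    def n_pre(self, rate_hz: float) -> int:
        return int(round(self.pre_ms * rate_hz / 1000.0))

    def n_ict(self, rate_hz: float) -> int:
        return int(round(self.ict_ms * rate_hz / 1000.0))


@dataclass
class WindowPair:
    """Preictal [onset-pre, onset) and ictal [onset, onset+ict) segments."""

    preictal: np.ndarray
    ictal: np.ndarray
    event: SwdEvent
    rate_hz: float
    channel_names: list[str] = field(default_factory=lambda: list(CANONICAL_16))


def write_annotations(events: list[SwdEvent], path: str | Path) -> None:
    rows = [
        {
            "patient_id": ev.patient_id,
            "swd_id": ev.swd_id,
            "onset_s": ev.onset_s,
            "offset_s": ev.offset_s,
            "label": "" if ev.label is None else ev.label,
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[SwdEvent]:
    path = Path(path)
    if not path.exists():
        raise EegIoError(f"annotation file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise EegIoError(f"malformed annotation CSV {path}: {exc}") from exc
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise EegIoError(f"annotation CSV missing columns: {missing}")
    events = []
    for _, row in df.iterrows():
        label = row["label"]
        label = None if pd.isna(label) or label == "" else int(label)
        events.append(
            SwdEvent(
                patient_id=str(row["patient_id"]),
                swd_id=str(row["swd_id"]),
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
                label=label,
            )
        )
    return events


def read_recording(
    edf_path: str | Path,
    annotations: str | Path | None = None,
    patient_id: str | None = None,
) -> tuple[Recording, list[SwdEvent]]:
    """Load one EDF file plus the annotation rows belonging to its patient.

    Sample values are returned in µV. Events are validated against the
    recording duration; an out-of-range event is a hard error because it
    indicates mismatched files rather than a borderline window.
    """
    edf_path = Path(edf_path)
    if not edf_path.exists():
        raise EegIoError(f"EDF file not found: {edf_path}")
    import mne

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # volts -> µV
    names = [normalize_label(n) for n in raw.ch_names]
    pid = patient_id if patient_id is not None else edf_path.stem
    rec = Recording(samples=samples, rate_hz=float(raw.info["sfreq"]),
                    channel_names=names, patient_id=pid)

    events: list[SwdEvent] = []
    if annotations is not None:
        for ev in read_annotations(annotations):
            if ev.patient_id != rec.patient_id:
                continue
            if ev.offset_s > rec.duration_s + 1e-9:
                raise EegIoError(
                    f"event {ev.swd_id} ends at {ev.offset_s:.3f}s, beyond the "
                    f"{rec.duration_s:.3f}s recording of {rec.patient_id}"
                )
            events.append(ev)
    return rec, events


def _bandpass(samples: np.ndarray, rate_hz: float, lo: float, hi: float) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, samples, axis=1)


def preprocess(
    rec: Recording,
    target_rate_hz: float = 256.0,
    reference: Reference | str = Reference.common_average,
    channel_subset: list[str] | None = None,
    bandpass: bool = True,
) -> Recording:
    """Harmonize a recording: channel subset, band-pass, resample, re-reference.

    The band-pass is 0.5 Hz to min(100, Nyquist-1) Hz; resampling is
    polyphase (anti-aliased); the channel order of the output follows the
    requested subset (canonical 16-channel order by default).
    """
    if isinstance(reference, str):
        reference = Reference(reference)
    subset = list(channel_subset) if channel_subset is not None else list(CANONICAL_16)
    subset = [normalize_label(c) for c in subset]
    have = {normalize_label(n): i for i, n in enumerate(rec.channel_names)}
    missing = [c for c in subset if c not in have]
    if missing:
        raise EegIoError(f"channels not present in recording: {missing}")
    if target_rate_hz > rec.rate_hz:
        raise EegIoError("target rate must not exceed the native rate")

    x = rec.samples[[have[c] for c in subset], :]
    if bandpass:
        hi = min(100.0, rec.rate_hz / 2 - 1.0)
        x = _bandpass(x, rec.rate_hz, 0.5, hi)
    if target_rate_hz != rec.rate_hz:
        up = int(round(target_rate_hz))
        down = int(round(rec.rate_hz))
        g = np.gcd(up, down)
        x = sps.resample_poly(x, up // g, down // g, axis=1)
    if reference == Reference.common_average:
        x = x - x.mean(axis=0, keepdims=True)
    elif reference == Reference.Cz:
        raise EegIoError(
            "Cz re-referencing requires a Cz channel, which is outside the "
            "16-channel subset; preprocess before subsetting instead"
        )
    return Recording(samples=x, rate_hz=float(target_rate_hz), channel_names=subset,
                     patient_id=rec.patient_id, reference=reference)


def extract_windows(rec: Recording, event: SwdEvent, cfg: WindowConfig) -> WindowPair:
    """Cut the [onset-pre, onset) and [onset, onset+ict) windows of one event.

    Half-open windows; the onset sample belongs to the ictal window. An event
    whose preictal context would start before the recording (or whose ictal
    window runs past its end) raises :class:`WindowExtractionError` so batch
    callers can skip it with a warning instead of zero-padding.
    """
    onset_idx = int(round(event.onset_s * rec.rate_hz))
    n_pre = cfg.n_pre(rec.rate_hz)
    n_ict = cfg.n_ict(rec.rate_hz)
    if onset_idx - n_pre < 0:
        raise WindowExtractionError(
            f"event {event.swd_id}: onset {event.onset_s:.3f}s leaves no room "
            f"for a {cfg.pre_ms:.0f} ms preictal window"
        )
    if onset_idx + n_ict > rec.n_samples:
        raise WindowExtractionError(
            f"event {event.swd_id}: ictal window runs past the recording end"
        )
    return WindowPair(
        preictal=rec.samples[:, onset_idx - n_pre : onset_idx].copy(),
        ictal=rec.samples[:, onset_idx : onset_idx + n_ict].copy(),
        event=event,
        rate_hz=rec.rate_hz,
        channel_names=list(rec.channel_names),
    )


def extract_window_pairs(
    recordings: list[Recording],
    events: list[SwdEvent],
    cfg: WindowConfig,
) -> list[WindowPair]:
    """Windows for every extractable event; skips (and warns about) the rest."""
    by_patient = {r.patient_id: r for r in recordings}
    out = []
    for ev in events:
        rec = by_patient.get(ev.patient_id)
        if rec is None:
            warnings.warn(f"no recording for patient {ev.patient_id}; "
                          f"event {ev.swd_id} skipped")
            continue
        try:
            out.append(extract_windows(rec, ev, cfg))
        except WindowExtractionError as exc:
            warnings.warn(str(exc))
    return out
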