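"""Deterministic EEG signal conditioning.

Resampling, average referencing, zero-phase band-pass filtering, epoching,
moving-window peak-to-peak artifact rejection and bad-channel detection —
the reproducible subset of a conventional sensor-space cleaning chain.
Stochastic steps that depend on trained classifiers (ICA component
labelling) are intentionally out of scope; the analysis pipeline enters at
parcel-level signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .simulate import EpochArray

logger = logging.getLogger(__name__)

__all__ = [
    "ContinuousRecording",
    "RejectionReport",
    "resample",
    "average_reference",
    "bandpass",
    "bandpass_response",
    "epoch",
    "reject_peak_to_peak",
    "detect_bad_channels",
    "read_raw_recording",
]


@dataclass
class ContinuousRecording:
    """Continuous multichannel recording with stimulus events.

    ``data`` is channels x samples in microvolts; ``events`` is a list of
    ``(sample_index, code)`` pairs with strictly increasing latencies.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        lats = [lat for lat, _ in self.events]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise ValueError("event latencies must be strictly increasing")
        if lats and (lats[0] < 0 or lats[-1] >= self.data.shape[1]):
            raise ValueError("event latencies must lie within the record")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class RejectionReport:
    """Outcome of epoch-level artifact screening."""

    kept_mask: np.ndarray
    offending_channel: list[str | None]

    @property
    def retained_fraction(self) -> float:
        return float(np.mean(self.kept_mask)) if self.kept_mask.size else 1.0


def resample(rec: ContinuousRecording, target_fs: float) -> ContinuousRecording:
    """Polyphase resampling with proportional event remapping."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs_hz:
        return ContinuousRecording(
            rec.data.copy(), rec.fs_hz, list(rec.channel_labels), list(rec.events)
        )
    if target_fs > rec.fs_hz:
        logger.warning("upsampling %g -> %g Hz", rec.fs_hz, target_fs)
    frac = Fraction(target_fs / rec.fs_hz).limit_denominator(1000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    ratio = target_fs / rec.fs_hz
    events = [
        (int(round(lat * ratio)), code)
        for lat, code in rec.events
        if int(round(lat * ratio)) < out.shape[1]
    ]
    return ContinuousRecording(out, target_fs, list(rec.channel_labels), events)


def average_reference(rec: ContinuousRecording) -> ContinuousRecording:
    """Re-reference to the per-sample mean across channels."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires >= 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return ContinuousRecording(out, rec.fs_hz, list(rec.channel_labels), list(rec.events))


def _butter_sos(low_hz: float, high_hz: float, fs_hz: float, order: int = 4):
    nyq = fs_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"band ({low_hz}, {high_hz}) must lie inside (0, {nyq})")
    return sps.butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")


def bandpass(rec_or_epochs, low_hz: float, high_hz: float, order: int = 4):
    """Zero-phase Butterworth band-pass (forward-backward).

    Zero phase is required because the filtered signal feeds phase-based
    connectivity estimation.  Accepts either a ``ContinuousRecording`` or
    an ``EpochArray`` and returns the same type.
    """
    if isinstance(rec_or_epochs, ContinuousRecording):
        sos = _butter_sos(low_hz, high_hz, rec_or_epochs.fs_hz, order)
        out = sps.sosfiltfilt(sos, rec_or_epochs.data, axis=1)
        return ContinuousRecording(
            out,
            rec_or_epochs.fs_hz,
            list(rec_or_epochs.channel_labels),
            list(rec_or_epochs.events),
        )
    if isinstance(rec_or_epochs, EpochArray):
        sos = _butter_sos(low_hz, high_hz, rec_or_epochs.fs_hz, order)
        out = sps.sosfiltfilt(sos, rec_or_epochs.data, axis=2)
        return EpochArray(
            out, rec_or_epochs.fs_hz, rec_or_epochs.t0_s, rec_or_epochs.node_labels
        )
    raise TypeError("expected ContinuousRecording or EpochArray")


def bandpass_response(
    low_hz: float, high_hz: float, fs_hz: float, order: int = 4, n_freqs: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Realized zero-phase transfer function (|H|^2 of the one-pass filter)."""
    sos = _butter_sos(low_hz, high_hz, fs_hz, order)
    freqs, h = sps.sosfreqz(sos, worN=n_freqs, fs=fs_hz)
    return freqs, np.abs(h) ** 2


def epoch(rec: ContinuousRecording, tmin_s: float, tmax_s: float) -> EpochArray:
    """Segment around events into fixed-length epochs.

    Convention (inclusive endpoints): the first sample of each epoch is at
    ``round(tmin * fs)`` relative to the event and the epoch holds
    ``floor((tmax - tmin) * fs) + 1`` samples, e.g. 333 samples for a
    -0.5..0.8 s window at 256 Hz.  Events too close to the record edge are
    dropped with a warning.
    """
    if tmax_s <= tmin_s:
        raise ValueError("tmax_s must exceed tmin_s")
    if not rec.events:
        raise ValueError("recording has no events to epoch around")
    n_samp = int(np.floor((tmax_s - tmin_s) * rec.fs_hz)) + 1
    offset = int(round(tmin_s * rec.fs_hz))
    chunks = []
    for lat, code in rec.events:
        start = lat + offset
        stop = start + n_samp
        if start < 0 or stop > rec.n_samples:
            logger.warning("dropping epoch at sample %d (%s): outside record", lat, code)
            continue
        chunks.append(rec.data[:, start:stop])
    if not chunks:
        raise ValueError("no event leaves room for a full epoch")
    data = np.stack(chunks, axis=0)
    return EpochArray(
        data, fs_hz=rec.fs_hz, t0_s=tmin_s, node_labels=list(rec.channel_labels)
    )


def reject_peak_to_peak(
    epochs: EpochArray,
    threshold_uv: float = 100.0,
    win_ms: float = 200.0,
    step_ms: float = 20.0,
) -> RejectionReport:
    """Flag epochs with excessive peak-to-peak amplitude in any channel.

    A moving window (default 200 ms, advancing 20 ms; the last partial
    window is included) slides over each epoch; the epoch is rejected iff
    some channel's max-min within at least one window position exceeds
    ``threshold_uv``.
    """
    n_ep, n_ch, n_samp = epochs.data.shape
    win = max(int(round(win_ms / 1000.0 * epochs.fs_hz)), 1)
    step = max(int(round(step_ms / 1000.0 * epochs.fs_hz)), 1)
    if win > n_samp:
        raise ValueError("window longer than epoch")
    starts = list(range(0, n_samp - win + 1, step))
    if starts[-1] + win < n_samp:  # trailing partial window
        starts.append(n_samp - win)

    kept = np.ones(n_ep, dtype=bool)
    offender: list[str | None] = [None] * n_ep
    labels = epochs.node_labels or [f"ch{i}" for i in range(n_ch)]
    for ei in range(n_ep):
        for ci in range(n_ch):
            x = epochs.data[ei, ci]
            p2p = max(
                x[s : s + win].max() - x[s : s + win].min() for s in starts
            )
            if p2p > threshold_uv:
                kept[ei] = False
                offender[ei] = labels[ci]
                break
    return RejectionReport(kept_mask=kept, offending_channel=offender)


def detect_bad_channels(
    rec: ContinuousRecording,
    corr_threshold: float = 0.85,
    line_noise_sd: float = 4.0,
    line_split_hz: float = 45.0,
) -> list[str]:
    """Flag channels by low neighbour correlation or excess line noise.

    A channel is bad if its maximal Pearson correlation with any other
    channel falls below ``corr_threshold``, or if its high/low frequency
    power ratio (above vs. below ``line_split_hz``) exceeds the across-
    channel mean by more than ``line_noise_sd`` standard deviations.
    Without a montage the "neighbourhood" is all other channels.
    """
    if rec.n_channels < 3:
        raise ValueError("bad-channel detection requires >= 3 channels")
    x = rec.data
    sd = x.std(axis=1)
    safe = np.where(sd > 0, sd, 1.0)
    z = (x - x.mean(axis=1, keepdims=True)) / safe[:, None]
    corr = (z @ z.T) / x.shape[1]
    np.fill_diagonal(corr, -np.inf)
    max_corr = corr.max(axis=1)

    freqs, psd = sps.welch(x, fs=rec.fs_hz, nperseg=min(x.shape[1], 1024), axis=1)
    hi = psd[:, freqs > line_split_hz].sum(axis=1)
    lo = psd[:, (freqs > 0) & (freqs <= line_split_hz)].sum(axis=1)
    ratio = hi / np.maximum(lo, 1e-30)
    noisy = ratio > ratio.mean() + line_noise_sd * ratio.std()

    bad = (max_corr < corr_threshold) | noisy
    return [lbl for lbl, b in zip(rec.channel_labels, bad) if b]


def read_raw_recording(path: str, events_csv: str | None = None) -> ContinuousRecording:
    """Read a real EDF/BDF sensor recording into a ContinuousRecording.

    Events come from the file's annotations or, if given, a two-column CSV
    (sample, code).  Delegates format parsing to MNE.
    """
    import mne  # deferred: heavy import, only needed for real data

    if path.lower().endswith(".bdf"):
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    events: list[tuple[int, str]] = []
    if events_csv is not None:
        import csv

        with open(events_csv, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().startswith("#"):
                    continue
                events.append((int(row[0]), row[1].strip() if len(row) > 1 else ""))
    else:
        for ann in raw.annotations:
            events.append((int(round(ann["onset"] * fs)), str(ann["description"])))
    events.sort(key=lambda t: t[0])
    return ContinuousRecording(data, fs, list(raw.ch_names), events)
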