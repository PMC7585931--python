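"""Field-potential analysis: epoching and evoked averages.

A 16-channel linear probe (100 um spacing) records continuously at
6 kHz during every experiment; the analysis reduces this to
stimulus-locked evoked averages over the mid-depth channels 3-8.
Channels are numbered 1-based at the interface, matching the probe
convention; storage is 0-based internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class NeuralRecord:
    """Multi-channel neural record.

    samples : (n_channels, n_samples), arbitrary units (uV for phantoms)
    events_s : stimulus pulse times, seconds on the record clock
    """

    samples: np.ndarray
    rate_hz: float
    channel_spacing_um: float = 100.0
    events_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        s = np.asarray(self.samples)
        if s.ndim != 2:
            raise ValidationError("samples must be (channels, time)")
        if self.rate_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        ev = np.asarray(self.events_s, dtype=float)
        if ev.size and (ev.min() < 0 or ev.max() > s.shape[1] / self.rate_hz):
            raise ValidationError("event times outside record")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "events_s", ev)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.rate_hz


def epoch_lfp(record: NeuralRecord, events_s: np.ndarray, pre_ms: float,
              post_ms: float) -> np.ndarray:
    """Pulse-aligned epochs, shape (n_trials, n_channels, n_samples).

    Events whose window overruns the record are excluded with a log
    entry; raises if none survive.
    """
    events_s = np.asarray(events_s, dtype=float)
    if events_s.size == 0:
        raise ValidationError("no events to epoch")
    n_pre = int(round(pre_ms / 1000.0 * record.rate_hz))
    n_post = int(round(post_ms / 1000.0 * record.rate_hz))
    n_total = record.samples.shape[1]
    epochs = []
    n_skipped = 0
    for t in events_s:
        c = int(round(t * record.rate_hz))
        if c - n_pre < 0 or c + n_post > n_total:
            n_skipped += 1
            continue
        epochs.append(record.samples[:, c - n_pre:c + n_post])
    if n_skipped:
        log.info("epoch_lfp: %d event(s) excluded (window outside record)",
                 n_skipped)
    if not epochs:
        raise ValidationError("all epochs fall outside the record")
    return np.stack(epochs).astype(float)


def evoked_field_potential(epochs: np.ndarray,
                           channels: tuple[int, int] = (3, 8)) -> np.ndarray:
    """Trial mean then channel mean over an inclusive 1-based channel range.

    The default (3, 8) reproduces the mid-depth average the evoked
    figures report.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValidationError("epochs must be (trials, channels, time)")
    lo, hi = channels
    n_ch = epochs.shape[1]
    if not (1 <= lo <= hi <= n_ch):
        raise ValidationError(
            f"channel range {channels} invalid for {n_ch} channels (1-based)"
        )
    return epochs.mean(axis=0)[lo - 1:hi].mean(axis=0)


def impulse_response(epochs: np.ndarray, pulse_times_s: np.ndarray,
                     rate_hz: float, window_s: float | None = None,
                     channels: tuple[int, int] = (3, 8)) -> np.ndarray:
    """Average single-deflection response within stimulus trains.

    Re-epochs each trial around every individual pulse (times relative
    to the trial epoch start) and averages across pulses and trials over
    the requested channel range.  If the requested window exceeds the
    inter-pulse interval it is clipped with a log entry.
    """
    epochs = np.asarray(epochs, dtype=float)
    pulse_times_s = np.asarray(pulse_times_s, dtype=float)
    if pulse_times_s.size == 0:
        raise ValidationError("need at least one pulse per trial")
    n_time = epochs.shape[2]
    if window_s is None:
        if pulse_times_s.size > 1:
            window_s = float(np.min(np.diff(np.sort(pulse_times_s))))
        else:
            window_s = (n_time / rate_hz) - float(pulse_times_s[0])
    n_win = int(round(window_s * rate_hz))
    sub = []
    for p in pulse_times_s:
        s0 = int(round(p * rate_hz))
        s1 = s0 + n_win
        if s1 > n_time:
            log.info("impulse_response: window clipped at record end")
            s1 = n_time
        if s1 > s0:
            sub.append(epochs[:, :, s0:s1][:, :, :n_win])
    n_min = min(s.shape[2] for s in sub)
    stacked = np.concatenate([s[:, :, :n_min] for s in sub], axis=0)
    return evoked_field_potential(stacked, channels)
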