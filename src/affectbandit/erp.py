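"""ERP extraction: filtering, epoching, baseline, rejection, mean amplitudes.

The pipeline mirrors a conventional stimulus-locked ERP analysis for this
task: continuous multichannel EEG (µV, 1000 Hz) is band-limited to
0.1-40 Hz with a zero-phase 4th-order Butterworth filter, segmented into
epochs of -100..500 ms around facial-prime onsets and -100..900 ms around
feedback onsets, baseline-corrected against the -100..0 ms prestimulus
mean, and epochs with any sample exceeding +/-50 µV on an analysis channel
are rejected.  Component amplitudes are mean activities over fixed windows:

* N170: 150-210 ms at P7/P8 (structural encoding of faces),
* P200: 170-230 ms at Fz/Cz/Pz (early affective appraisal),
* FRN:  300-600 ms at Fz/FCz/Cz on the unexpected-loss minus
  unexpected-win difference wave (reward prediction error signalling).

All windows use a half-open [start, end) convention at sample resolution;
0 ms is the first poststimulus sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .errors import ConfigurationError, DataError
from .task import POOR, RICH, TrialRecord

#: channels entering artifact rejection and component statistics
ANALYSIS_CHANNELS = ("P7", "P8", "Fz", "FCz", "Cz", "Pz")

EXPECTED_WIN = "expected_win"
UNEXPECTED_WIN = "unexpected_win"
EXPECTED_LOSS = "expected_loss"
UNEXPECTED_LOSS = "unexpected_loss"

#: integer event codes used in ContinuousEEG event lists
EVENT_CODES = {
    "prime": 1,
    EXPECTED_WIN: 20,
    UNEXPECTED_WIN: 21,
    EXPECTED_LOSS: 22,
    UNEXPECTED_LOSS: 23,
}


@dataclass(frozen=True)
class ComponentWindows:
    """Named analysis windows (ms) and channel sets."""

    n170_window: tuple[float, float] = (150.0, 210.0)
    n170_channels: tuple[str, ...] = ("P7", "P8")
    p200_window: tuple[float, float] = (170.0, 230.0)
    p200_channels: tuple[str, ...] = ("Fz", "Cz", "Pz")
    frn_window: tuple[float, float] = (300.0, 600.0)
    frn_channels: tuple[str, ...] = ("Fz", "FCz", "Cz")
    prime_epoch: tuple[float, float] = (-100.0, 500.0)
    feedback_epoch: tuple[float, float] = (-100.0, 900.0)
    baseline: tuple[float, float] = (-100.0, 0.0)

    def __post_init__(self) -> None:
        for window, epoch in (
            (self.n170_window, self.prime_epoch),
            (self.p200_window, self.prime_epoch),
            (self.frn_window, self.feedback_epoch),
        ):
            if not (epoch[0] <= window[0] < window[1] <= epoch[1]):
                raise ConfigurationError(f"window {window} must lie inside epoch {epoch}")


DEFAULT_WINDOWS = ComponentWindows()


@dataclass
class ContinuousEEG:
    """Continuous multichannel record in µV with an event list.

    ``events`` is an (n_events, 2) integer array of (sample index, code).
    """

    data: np.ndarray  # (n_channels, n_samples), µV
    channels: tuple[str, ...]
    sfreq: float = 1000.0
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise DataError("data must be (n_channels, n_samples) matching channel labels")
        if self.sfreq <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if len(self.events) and (
            self.events[:, 0].min() < 0 or self.events[:, 0].max() >= self.data.shape[1]
        ):
            raise DataError("event samples must lie within the record")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, names: Iterable[str]) -> list[int]:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ConfigurationError(f"channels not present: {missing}")
        return [self.channels.index(n) for n in names]


@dataclass
class EpochSet:
    """Epochs x channels x time array with window metadata and rejection mask."""

    data: np.ndarray  # (n_epochs, n_channels, n_times), µV
    channels: tuple[str, ...]
    sfreq: float
    window_ms: tuple[float, float]  # half-open [start, end)
    event_codes: np.ndarray  # (n_epochs,)
    mask: np.ndarray = None  # True = retained
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(len(self.data), dtype=bool)

    @property
    def n_epochs(self) -> int:
        return len(self.data)

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        return self.window_ms[0] + step * np.arange(self.data.shape[2])

    def channel_index(self, names: Iterable[str]) -> list[int]:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ConfigurationError(f"channels not present: {missing}")
        return [self.channels.index(n) for n in names]


@dataclass
class ErpWaveform:
    """Average waveform (channels x time, µV) over retained epochs."""

    data: np.ndarray  # (n_channels, n_times)
    channels: tuple[str, ...]
    sfreq: float
    window_ms: tuple[float, float]
    n_epochs: int
    label: str = ""

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        return self.window_ms[0] + step * np.arange(self.data.shape[1])

    def channel_index(self, names: Iterable[str]) -> list[int]:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ConfigurationError(f"channels not present: {missing}")
        return [self.channels.index(n) for n in names]


def bandpass(
    eeg: ContinuousEEG, low: float = 0.1, high: float = 40.0, order: int = 4
) -> ContinuousEEG:
    """Zero-phase Butterworth band-pass; events are preserved."""
    nyquist = eeg.sfreq / 2.0
    if not (0.0 < low < high < nyquist):
        raise ConfigurationError(
            f"band must satisfy 0 < low < high < Nyquist ({nyquist} Hz), got {low}-{high}"
        )
    sos = signal.butter(order, [low, high], btype="band", fs=eeg.sfreq, output="sos")
    # single-precision input stays single precision (large records filter ~5x faster)
    if eeg.data.dtype == np.float32:
        sos = sos.astype(np.float32)
    filtered = signal.sosfiltfilt(sos, eeg.data, axis=1)
    return ContinuousEEG(
        data=filtered, channels=eeg.channels, sfreq=eeg.sfreq, events=eeg.events.copy()
    )


def epoch(
    eeg: ContinuousEEG,
    event_code: int | Sequence[int],
    window_ms: tuple[float, float],
) -> EpochSet:
    """Cut epochs around events of the given code(s).

    Sample 0 of each epoch corresponds to the window start; events whose
    window does not fit inside the record are skipped and counted.
    """
    codes = (event_code,) if np.isscalar(event_code) else tuple(event_code)
    t0, t1 = window_ms
    offset0 = int(round(t0 * eeg.sfreq / 1000.0))
    n_times = int(round((t1 - t0) * eeg.sfreq / 1000.0))
    epochs, kept_codes, n_skipped = [], [], 0
    for sample, code in eeg.events:
        if code not in codes:
            continue
        start = sample + offset0
        if start < 0 or start + n_times > eeg.n_samples:
            n_skipped += 1
            continue
        epochs.append(eeg.data[:, start : start + n_times])
        kept_codes.append(code)
    if not epochs:
        raise DataError(
            f"no usable events with code(s) {codes} (skipped {n_skipped} at record edges)"
        )
    return EpochSet(
        data=np.stack(epochs), channels=eeg.channels, sfreq=eeg.sfreq,
        window_ms=(float(t0), float(t1)), event_codes=np.array(kept_codes),
        n_skipped=n_skipped,
    )


def baseline_correct(
    epochs: EpochSet, baseline_ms: tuple[float, float] = DEFAULT_WINDOWS.baseline
) -> EpochSet:
    """Subtract the per-epoch, per-channel mean of the prestimulus window."""
    t0, _ = epochs.window_ms
    b0, b1 = baseline_ms
    i0 = int(round((b0 - t0) * epochs.sfreq / 1000.0))
    i1 = int(round((b1 - t0) * epochs.sfreq / 1000.0))
    if i0 < 0 or i1 <= i0 or i1 > epochs.data.shape[2]:
        raise ConfigurationError(
            f"baseline window {baseline_ms} has no samples inside epoch {epochs.window_ms}"
        )
    baseline = epochs.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return EpochSet(
        data=epochs.data - baseline, channels=epochs.channels, sfreq=epochs.sfreq,
        window_ms=epochs.window_ms, event_codes=epochs.event_codes.copy(),
        mask=epochs.mask.copy(), n_skipped=epochs.n_skipped,
    )


def reject_artifacts(
    epochs: EpochSet,
    threshold_uv: float = 50.0,
    channels: Sequence[str] | None = None,
) -> EpochSet:
    """Reject epochs with any sample strictly exceeding the +/-threshold.

    Evaluated on the analysis channels present in the data by default;
    exactly +/-threshold is retained.  The mask depends only on the samples
    and the threshold, never on event labels.
    """
    if channels is None:
        channels = [c for c in ANALYSIS_CHANNELS if c in epochs.channels] or list(epochs.channels)
    idx = epochs.channel_index(channels)
    bad = np.any(np.abs(epochs.data[:, idx, :]) > threshold_uv, axis=(1, 2))
    return EpochSet(
        data=epochs.data, channels=epochs.channels, sfreq=epochs.sfreq,
        window_ms=epochs.window_ms, event_codes=epochs.event_codes.copy(),
        mask=epochs.mask & ~bad, n_skipped=epochs.n_skipped,
    )


def classify_feedback(trial: TrialRecord | tuple[str, int]) -> str:
    """Expectancy class of a feedback event from deck class and outcome.

    Rewards from the poor deck and omissions from the rich deck are the
    unexpected outcomes; their counterparts are expected.
    """
    if isinstance(trial, TrialRecord):
        deck_class, reward = trial.deck_class, trial.reward
    else:
        deck_class, reward = trial
    if deck_class not in (RICH, POOR):
        raise DataError(f"deck_class must be '{RICH}' or '{POOR}', got {deck_class!r}")
    if deck_class == POOR:
        return UNEXPECTED_WIN if reward == 1 else EXPECTED_LOSS
    return EXPECTED_WIN if reward == 1 else UNEXPECTED_LOSS


def average_erp(
    epochs: EpochSet,
    selector: np.ndarray | int | Sequence[int] | None = None,
    label: str = "",
) -> ErpWaveform:
    """Pointwise mean over retained epochs, optionally restricted by event
    code(s) or a boolean selector aligned with the epochs."""
    select = epochs.mask.copy()
    if selector is not None:
        if isinstance(selector, np.ndarray) and selector.dtype == bool:
            select &= selector
        else:
            codes = (selector,) if np.isscalar(selector) else tuple(selector)
            select &= np.isin(epochs.event_codes, codes)
    if not select.any():
        raise DataError(
            f"no retained epochs match selector (retained {epochs.n_retained} "
            f"of {epochs.n_epochs})"
        )
    return ErpWaveform(
        data=epochs.data[select].mean(axis=0), channels=epochs.channels,
        sfreq=epochs.sfreq, window_ms=epochs.window_ms,
        n_epochs=int(select.sum()), label=label,
    )


def frn_difference(loss_erp: ErpWaveform, win_erp: ErpWaveform) -> ErpWaveform:
    """Unexpected-loss minus unexpected-win difference wave."""
    if (
        loss_erp.channels != win_erp.channels
        or loss_erp.sfreq != win_erp.sfreq
        or loss_erp.window_ms != win_erp.window_ms
        or loss_erp.data.shape != win_erp.data.shape
    ):
        raise DataError("loss and win waveforms must share channels, window, and rate")
    return ErpWaveform(
        data=loss_erp.data - win_erp.data, channels=loss_erp.channels,
        sfreq=loss_erp.sfreq, window_ms=loss_erp.window_ms,
        n_epochs=min(loss_erp.n_epochs, win_erp.n_epochs),
        label="frn_difference",
    )


def mean_amplitude(
    erp: ErpWaveform, window_ms: tuple[float, float], channels: Sequence[str]
) -> float:
    """Mean µV over a half-open time window, channels averaged equally."""
    t0, t1 = erp.window_ms
    w0, w1 = window_ms
    i0 = int(round((w0 - t0) * erp.sfreq / 1000.0))
    i1 = int(round((w1 - t0) * erp.sfreq / 1000.0))
    if i0 < 0 or i1 > erp.data.shape[1] or i1 <= i0:
        raise ConfigurationError(f"window {window_ms} lies outside epoch {erp.window_ms}")
    idx = erp.channel_index(channels)
    return float(erp.data[idx, i0:i1].mean())


def extract_component_amplitudes(
    eeg: ContinuousEEG,
    windows: ComponentWindows = DEFAULT_WINDOWS,
    apply_bandpass: bool = True,
    rejection_threshold_uv: float = 50.0,
) -> dict[str, float]:
    """Run the full pipeline on one continuous record and return component
    amplitudes.

    Returns ``n170``, ``p200`` (prime-locked) and ``frn`` (the
    unexpected-loss minus unexpected-win difference wave), plus epoch
    bookkeeping counts.  ``frn`` is NaN when either unexpected class has no
    retained epochs.
    """
    record = bandpass(eeg) if apply_bandpass else eeg

    prime = baseline_correct(
        epoch(record, EVENT_CODES["prime"], windows.prime_epoch), windows.baseline
    )
    prime = reject_artifacts(prime, rejection_threshold_uv)
    prime_avg = average_erp(prime, label="prime")
    out = {
        "n170": mean_amplitude(prime_avg, windows.n170_window, windows.n170_channels),
        "p200": mean_amplitude(prime_avg, windows.p200_window, windows.p200_channels),
        "n_prime_epochs": float(prime.n_retained),
    }

    feedback_codes = [EVENT_CODES[c] for c in
                      (EXPECTED_WIN, UNEXPECTED_WIN, EXPECTED_LOSS, UNEXPECTED_LOSS)]
    feedback = baseline_correct(
        epoch(record, feedback_codes, windows.feedback_epoch), windows.baseline
    )
    feedback = reject_artifacts(feedback, rejection_threshold_uv)
    n_loss = int((feedback.mask & (feedback.event_codes == EVENT_CODES[UNEXPECTED_LOSS])).sum())
    n_win = int((feedback.mask & (feedback.event_codes == EVENT_CODES[UNEXPECTED_WIN])).sum())
    out.update({"n_unexpected_loss": float(n_loss), "n_unexpected_win": float(n_win)})
    if n_loss == 0 or n_win == 0:
        out["frn"] = float("nan")
        return out
    loss = average_erp(feedback, EVENT_CODES[UNEXPECTED_LOSS], label=UNEXPECTED_LOSS)
    win = average_erp(feedback, EVENT_CODES[UNEXPECTED_WIN], label=UNEXPECTED_WIN)
    diff = frn_difference(loss, win)
    out["frn"] = mean_amplitude(diff, windows.frn_window, windows.frn_channels)
    return out
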