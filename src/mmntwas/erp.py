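"""Mismatch-negativity extraction from averaged event-related potentials.

The MMN is the negative trough of the deviant-minus-standard difference
wave.  Averaged standard and deviant waveforms are subtracted pointwise,
baseline-corrected over a pre-stimulus window, and the windowed peak is the
global minimum within a cohort-specific post-stimulus search window
(50-200 ms for short-stimulus cohorts, 100-250 ms for the long-stimulus
cohort), with ties broken by the earliest latency.  Amplitudes are read at
sample resolution; no sub-sample interpolation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import EpochSet

__all__ = [
    "Waveform",
    "MmnMeasure",
    "PEAK_WINDOWS",
    "difference_wave",
    "baseline_correct",
    "detect_mmn_peak",
    "average_epochs",
    "measure_epochs",
    "read_waveforms_tsv",
    "write_waveforms_tsv",
]

# default peak-search windows (ms post-stimulus) by stimulus-duration class
PEAK_WINDOWS = {"short": (50.0, 200.0), "long": (100.0, 250.0)}
DEFAULT_BASELINE = (-100.0, 0.0)


@dataclass
class Waveform:
    """Uniformly sampled single-channel waveform in microvolts."""

    values: np.ndarray
    sampling_rate: float
    time_zero_index: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not 0 <= self.time_zero_index < self.values.size:
            raise ValueError("time_zero_index outside the waveform")

    @property
    def times(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        return step * (np.arange(self.values.size) - self.time_zero_index)


@dataclass
class MmnMeasure:
    amplitude: float  # uV, signed
    latency: float    # ms post-stimulus
    window: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.window
        if not (lo <= self.latency <= hi):
            raise ValueError("latency outside the search window")


def _check_compatible(a: Waveform, b: Waveform) -> None:
    if a.values.size != b.values.size:
        raise ValueError("waveform lengths differ")
    if a.sampling_rate != b.sampling_rate:
        raise ValueError("sampling rates differ")
    if a.time_zero_index != b.time_zero_index:
        raise ValueError("stimulus-onset indices differ")


def difference_wave(standard: Waveform, deviant: Waveform) -> Waveform:
    """Pointwise deviant minus standard."""
    _check_compatible(standard, deviant)
    return Waveform(
        deviant.values - standard.values, standard.sampling_rate, standard.time_zero_index
    )


def baseline_correct(w: Waveform, baseline_window: tuple[float, float] = DEFAULT_BASELINE) -> Waveform:
    """Subtract the mean over the (pre-stimulus) baseline window.

    Idempotent; the corrected waveform has exactly zero baseline mean.
    """
    lo, hi = baseline_window
    t = w.times
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError(f"baseline window {baseline_window} contains no samples")
    return Waveform(w.values - w.values[mask].mean(), w.sampling_rate, w.time_zero_index)


def detect_mmn_peak(w: Waveform, window: tuple[float, float]) -> MmnMeasure:
    """Global minimum of the waveform within a post-stimulus window.

    Latency ties (equal-depth minima) resolve to the earliest sample.
    """
    lo, hi = window
    if lo < 0:
        raise ValueError("peak window must start at or after stimulus onset")
    t = w.times
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError(f"peak window {window} outside the epoch")
    idx = np.flatnonzero(mask)
    j = idx[np.argmin(w.values[idx])]  # argmin returns the first minimum
    return MmnMeasure(float(w.values[j]), float(t[j]), (lo, hi))


def average_epochs(epochs: EpochSet) -> tuple[Waveform, Waveform]:
    """Trial-average the standard and deviant epochs into waveforms."""
    t0 = int(round(-epochs.epoch_window[0] * epochs.sampling_rate / 1000.0))

    def _mean(trials):
        # anchored at the first trial: exact when all trials coincide
        # (zero-noise data), and better centered numerically otherwise
        return trials[0] + (trials - trials[0]).mean(axis=0)

    std = Waveform(_mean(epochs.standard_epochs), epochs.sampling_rate, t0)
    dev = Waveform(_mean(epochs.deviant_epochs), epochs.sampling_rate, t0)
    return std, dev


def measure_epochs(
    epochs: EpochSet,
    window: tuple[float, float] | None = None,
    *,
    stimulus_class: str = "short",
    baseline_window: tuple[float, float] = DEFAULT_BASELINE,
) -> MmnMeasure:
    """Full extraction: average, difference, baseline-correct, detect peak.

    The search window defaults to the stimulus-duration class convention
    (``PEAK_WINDOWS``); pass ``window`` to override.
    """
    if window is None:
        window = PEAK_WINDOWS[stimulus_class]
    std, dev = average_epochs(epochs)
    diff = baseline_correct(difference_wave(std, dev), baseline_window)
    return detect_mmn_peak(diff, window)


def read_waveforms_tsv(path) -> dict[str, Waveform]:
    """Read waveforms from a TSV with a ``time_ms`` column plus one column
    per condition; the time axis must be uniform and include 0 ms."""
    df = pd.read_csv(path, sep="\t")
    if "time_ms" not in df.columns:
        raise ValueError("waveform TSV requires a 'time_ms' column")
    t = df["time_ms"].to_numpy(dtype=float)
    steps = np.diff(t)
    if t.size < 2 or not np.allclose(steps, steps[0]):
        raise ValueError("time axis must be strictly increasing and uniform")
    rate = 1000.0 / steps[0]
    zero = int(np.argmin(np.abs(t)))
    if abs(t[zero]) > 1e-6:
        raise ValueError("time axis must include 0 ms (stimulus onset)")
    return {
        c: Waveform(df[c].to_numpy(dtype=float), rate, zero)
        for c in df.columns
        if c != "time_ms"
    }


def write_waveforms_tsv(waves: dict[str, Waveform], path) -> None:
    first = next(iter(waves.values()))
    for w in waves.values():
        _check_compatible(first, w)
    out = pd.DataFrame({"time_ms": first.times})
    for name, w in waves.items():
        out[name] = w.values
    out.to_csv(path, sep="\t", index=False)
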