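"""Documented cleaning steps for epoched EEG.

Three operations, applied per epoch: a zero-phase 1-50 Hz Butterworth
bandpass, re-referencing to the channel average, and amplitude-threshold
artifact rejection (epochs with any sample strictly exceeding +/-100 uV are
flagged and excluded downstream, never deleted).

The original recordings were filtered continuously before segmentation;
operating on already-segmented epochs introduces edge transients that the
forward-backward (zero-phase) filter keeps small and latency-free.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import signal

from .containers import EpochTensor, RejectionLog

__all__ = ["bandpass_filter", "rereference_average", "reject_artifacts", "preprocess_cohort"]


def design_bandpass(low: float, high: float, sample_rate: float, order: int = 4):
    """(b, a) coefficients of the Butterworth bandpass used throughout."""
    nyq = sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist={nyq}) Hz")
    return signal.butter(order, [low, high], btype="bandpass", fs=sample_rate)


def bandpass_filter(epochs: EpochTensor, low: float = 1.0, high: float = 50.0,
                    order: int = 4) -> EpochTensor:
    """Zero-phase Butterworth bandpass applied per channel and epoch.

    Epochs are short (hundreds of samples) relative to the highpass edge's
    impulse response, so the forward-backward pass uses Gustafsson's
    initial-condition matching, which keeps edge transients negligible, after
    removing each epoch's mean (the DC offset the passband excludes anyway).
    """
    b, a = design_bandpass(low, high, epochs.sample_rate, order)
    demeaned = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    irlen = min(epochs.n_samples - 1, 120)
    filtered = signal.filtfilt(b, a, demeaned, axis=-1, method="gust", irlen=irlen)
    return epochs.with_data(np.ascontiguousarray(filtered))


def rereference_average(epochs: EpochTensor) -> EpochTensor:
    """Subtract the instantaneous mean over channels (average reference)."""
    if epochs.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    mean = epochs.data.mean(axis=2, keepdims=True)
    return epochs.with_data(epochs.data - mean)


def reject_artifacts(epochs: EpochTensor, threshold: float = 100.0) -> tuple[EpochTensor, RejectionLog]:
    """Flag epochs whose peak absolute voltage strictly exceeds ``threshold``.

    "Exceeding +/- threshold" is read as a strict inequality: an epoch whose
    extreme sample equals the threshold exactly is kept.  The returned tensor
    shares voltage data with the input but carries an updated ``kept`` mask;
    the log records the rejected (stimulus, presentation) pairs (0-based).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peak = np.max(np.abs(epochs.data), axis=(2, 3))
    keep = peak <= threshold
    kept = epochs.kept & keep
    rejected = [(int(s), int(p)) for s, p in zip(*np.nonzero(epochs.kept & ~keep))]
    log = RejectionLog(
        participant_id=epochs.participant_id,
        rejected=rejected,
        kept_count=int(kept.sum()),
        total_count=int(epochs.kept.sum()),
    )
    return replace(epochs, kept=kept), log


def preprocess_cohort(
    cohort: list[EpochTensor],
    low: float = 1.0,
    high: float = 50.0,
    reject_uv: float = 100.0,
) -> tuple[list[EpochTensor], list[RejectionLog]]:
    """Filter, re-reference and reject artifacts for every participant.

    Stage order follows the original analysis: bandpass filter, average
    reference, then amplitude-threshold rejection on the cleaned voltages.
    """
    out, logs = [], []
    for et in cohort:
        clean = rereference_average(bandpass_filter(et, low=low, high=high))
        clean, log = reject_artifacts(clean, threshold=reject_uv)
        out.append(clean)
        logs.append(log)
    return out, logs
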