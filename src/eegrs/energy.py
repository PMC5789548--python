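"""Normalized non-phase-locked signal energy.

Signal energy of an epoch is ``E = sum |amp|^2`` over all samples of the
0-800 ms window.  Before the energy is computed, two transforms are applied
per participant and channel:

1. **Evoked subtraction** (``mode='per_presentation_index'``): from each
   epoch ``(s, p)`` subtract the mean waveform over the 18 stimuli at the
   same presentation index ``p``.  The phase-locked evoked response is
   identical across stimuli and cancels; induced activity with random phase
   survives (retaining a fraction ``1 - 1/n_stimuli`` of its energy in
   expectation).  This isolates the non-phase-locked part of the response.

2. **Repetition-series normalization**: for each (participant, channel,
   stimulus), every sample of the 10-presentation series is divided by the
   pooled sample standard deviation (denominator N-1) of the whole series.
   This equalizes the scale of every pseudoword series, so energies are
   unitless and comparable across channels and participants; for a mean-zero
   normalized complete series the per-series energies sum to exactly
   ``10*T - 1``.

Rejected epochs are excluded from the subtraction average, from the
normalization pool and from the output table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochTensor, ParticipantMeta, ROISet

__all__ = [
    "subtract_evoked",
    "normalize_repetition_series",
    "compute_energy",
    "participant_energy",
    "energy_table",
]

EVOKED_MODES = ("none", "per_presentation_index")


class DegenerateSeriesError(ValueError):
    pass


def subtract_evoked(epochs: EpochTensor, mode: str = "per_presentation_index") -> EpochTensor:
    """Remove the phase-locked (evoked) component by cross-stimulus averaging."""
    if mode not in EVOKED_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {EVOKED_MODES}")
    if mode == "none":
        return epochs
    if epochs.n_stimuli < 2:
        raise ValueError("evoked subtraction requires at least 2 stimuli")
    w = epochs.kept[:, :, None, None].astype(float)
    counts = w.sum(axis=0, keepdims=True)
    mean = np.divide(
        (epochs.data * w).sum(axis=0, keepdims=True),
        counts,
        out=np.zeros((1,) + epochs.data.shape[1:]),
        where=counts > 0,
    )
    return epochs.with_data(epochs.data - mean)


@dataclass
class NormalizationRecord:
    participant_id: str
    channel: str
    stimulus: int  # 1-based
    sd_pooled: float

    def __post_init__(self):
        if not self.sd_pooled > 0:
            raise DegenerateSeriesError(
                f"constant repetition series (participant={self.participant_id}, "
                f"channel={self.channel}, stimulus={self.stimulus})"
            )


def normalize_repetition_series(series: np.ndarray, kept: np.ndarray | None = None,
                                participant_id: str = "", channel: str = "",
                                stimulus: int = 0) -> tuple[np.ndarray, NormalizationRecord]:
    """Scale one (presentations x samples) series to pooled sample SD 1.

    ``kept`` marks presentations included in the pool; excluded rows are
    returned as NaN.  The divisor is the sample SD (ddof=1) over all samples
    of all kept presentations pooled together.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be (presentations, samples)")
    if kept is None:
        kept = np.ones(series.shape[0], dtype=bool)
    pool = series[kept].ravel()
    if pool.size < 2:
        raise DegenerateSeriesError("fewer than 2 pooled samples")
    sd = float(np.std(pool, ddof=1))
    record = NormalizationRecord(participant_id, channel, stimulus, sd)
    out = np.full_like(series, np.nan)
    out[kept] = series[kept] / sd
    return out, record


def compute_energy(epoch: np.ndarray) -> float:
    """Signal energy of one epoch: sum of squared samples."""
    epoch = np.asarray(epoch, dtype=float)
    if not np.all(np.isfinite(epoch)):
        raise ValueError("epoch contains non-finite samples")
    return float(np.sum(np.square(epoch)))


def participant_energy(epochs: EpochTensor, mode: str = "per_presentation_index") -> np.ndarray:
    """Per-channel normalized energies for one participant.

    Returns an ``(n_stimuli, n_presentations, n_channels)`` array with NaN at
    rejected epochs.  Vectorized equivalent of running ``subtract_evoked`` ->
    ``normalize_repetition_series`` -> ``compute_energy`` over all
    (channel, stimulus) series.
    """
    x = subtract_evoked(epochs, mode=mode).data  # (S, P, C, T)
    S, P, C, T = x.shape
    w = epochs.kept[:, :, None, None].astype(float)  # (S, P, 1, 1)
    # pooled mean/SD per (stimulus, channel) over kept presentations and time
    n_pool = epochs.kept.sum(axis=1)[:, None] * T  # (S, 1) broadcast over channels
    s1 = (x * w).sum(axis=(1, 3))  # (S, C)
    s2 = (np.square(x) * w).sum(axis=(1, 3))  # (S, C)
    if np.any(n_pool < 2):
        raise DegenerateSeriesError("a repetition series has fewer than 2 pooled samples")
    var = (s2 - np.square(s1) / n_pool) / (n_pool - 1)
    if np.any(var <= 0):
        raise DegenerateSeriesError("constant repetition series encountered")
    raw_e = np.square(x).sum(axis=3)  # (S, P, C)
    e = raw_e / var[:, None, :]
    e[~epochs.kept] = np.nan
    return e


def energy_table(
    cohort: list[EpochTensor],
    metas: list[ParticipantMeta],
    rois: ROISet | None = None,
    mode: str = "per_presentation_index",
) -> pd.DataFrame:
    """Long-form energy table over a cohort.

    One row per (participant, stimulus, presentation, region) with columns
    ``participant_id, subgroup, stimulus, presentation, region, energy``
    (stimulus and presentation 1-based).  With ``rois=None`` the region
    column holds channel names; with an ROISet, the region energy is the
    unweighted mean of the member channels' energies.
    """
    meta_by_id = {m.participant_id: m for m in metas}
    frames = []
    for et in cohort:
        if et.participant_id not in meta_by_id:
            raise KeyError(f"no metadata for participant {et.participant_id!r}")
        e = participant_energy(et, mode=mode)  # (S, P, C)
        chan_index = {ch: i for i, ch in enumerate(et.channel_names)}
        if rois is not None:
            cols = []
            region_names = []
            for roi in rois:
                missing = [c for c in roi.channels if c not in chan_index]
                if missing:
                    raise KeyError(f"ROI {roi.name!r} references unknown channels {missing}")
                idx = [chan_index[c] for c in roi.channels]
                cols.append(e[:, :, idx].mean(axis=2))
                region_names.append(roi.name)
            values = np.stack(cols, axis=2)  # (S, P, R)
        else:
            values = e
            region_names = list(et.channel_names)
        S, P, R = values.shape
        s_idx, p_idx, r_idx = np.meshgrid(
            np.arange(S), np.arange(P), np.arange(R), indexing="ij"
        )
        flat = values.ravel()
        ok = np.isfinite(flat)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": et.participant_id,
                    "subgroup": meta_by_id[et.participant_id].subgroup,
                    "stimulus": s_idx.ravel()[ok] + 1,
                    "presentation": p_idx.ravel()[ok] + 1,
                    "region": np.asarray(region_names, dtype=object)[r_idx.ravel()[ok]],
                    "energy": flat[ok],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if (table["energy"] < 0).any():
        raise AssertionError("negative energy produced")  # defensive; impossible by construction
    return table
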