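"""Core data containers shared across the pipeline stages.

The central object is :class:`EpochTensor`, one participant's epoched EEG
voltages indexed ``(stimulus, presentation, channel, time)`` together with a
boolean ``kept`` mask that artifact rejection updates in place of deleting
data.  Participant-level covariates live in :class:`ParticipantMeta`;
electrode groupings derived from spatial factors live in :class:`ROISet`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

NVIQ_SPLIT = 42  # median split of the FXS group into low/high NVIQ subgroups

GROUPS = ("control", "fxs")
SUBGROUPS = ("control", "fxs_low", "fxs_high")


def subgroup_for(group: str, nviq: int, split: int = NVIQ_SPLIT) -> str:
    """Derive the NVIQ subgroup label from group membership and NVIQ score."""
    if group == "control":
        return "control"
    if group == "fxs":
        return "fxs_low" if nviq <= split else "fxs_high"
    raise ValueError(f"unknown group {group!r}")


@dataclass
class ParticipantMeta:
    """Group / NVIQ / age / sex labels for one participant."""

    participant_id: str
    group: str
    nviq: int
    age: float
    sex: str
    subgroup: str = ""

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        expected = subgroup_for(self.group, self.nviq)
        if not self.subgroup:
            self.subgroup = expected
        elif self.subgroup != expected:
            raise ValueError(
                f"subgroup {self.subgroup!r} inconsistent with group="
                f"{self.group!r}, nviq={self.nviq}"
            )


def meta_frame(metas: list[ParticipantMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in metas],
            "group": [m.group for m in metas],
            "nviq": [m.nviq for m in metas],
            "age": [m.age for m in metas],
            "sex": [m.sex for m in metas],
            "subgroup": [m.subgroup for m in metas],
        }
    )


@dataclass
class EpochTensor:
    """Epoched EEG voltages (microvolt) for one participant.

    ``data`` has shape ``(n_stimuli, n_presentations, n_channels, n_samples)``.
    ``kept[s, p]`` is False for epochs excluded by artifact rejection; the
    voltage data of rejected epochs is retained but ignored downstream.
    ``components`` optionally stores the generative ground truth (evoked /
    induced parts) for simulated data, used as an oracle in tests.
    """

    participant_id: str
    data: np.ndarray
    channel_names: list[str]
    sample_rate: float
    kept: np.ndarray = None
    components: dict | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (stimulus, presentation, channel, time)")
        if len(self.channel_names) != self.data.shape[2]:
            raise ValueError("channel_names length does not match data")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite voltages in epoch data")
        if self.kept is None:
            self.kept = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.kept = np.asarray(self.kept, dtype=bool)
            if self.kept.shape != self.data.shape[:2]:
                raise ValueError("kept mask shape mismatch")

    @property
    def n_stimuli(self) -> int:
        return self.data.shape[0]

    @property
    def n_presentations(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray, **kw) -> "EpochTensor":
        """Copy of this tensor with replaced voltage data (same indexing)."""
        return replace(self, data=data, **kw)


@dataclass
class RejectionLog:
    """Bookkeeping of amplitude-threshold epoch rejection for one participant."""

    participant_id: str
    rejected: list[tuple[int, int]]
    kept_count: int
    total_count: int

    def __post_init__(self):
        if self.kept_count + len(self.rejected) != self.total_count:
            raise ValueError("rejection log counts inconsistent")

    @staticmethod
    def to_frame(logs: list["RejectionLog"]) -> pd.DataFrame:
        rows = []
        for log in logs:
            rows.append(
                {
                    "participant_id": log.participant_id,
                    "n_rejected": len(log.rejected),
                    "kept_count": log.kept_count,
                    "total_count": log.total_count,
                    "rejected_epochs": ";".join(f"{s + 1},{p + 1}" for s, p in log.rejected),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ROI:
    """A named electrode set derived from one rotated spatial factor."""

    name: str
    channels: list[str]
    source_group: str
    factor_index: int

    def __post_init__(self):
        if not self.channels:
            raise ValueError(f"ROI {self.name!r} has no channels")


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def channels_of(self, name: str) -> list[str]:
        for r in self.rois:
            if r.name == name:
                return r.channels
        raise KeyError(name)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "name": r.name,
                "channels": list(r.channels),
                "source_group": r.source_group,
                "factor_index": r.factor_index,
            }
            for r in self.rois
        ]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ROISet":
        payload = json.loads(Path(path).read_text())
        return cls([ROI(**item) for item in payload])
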