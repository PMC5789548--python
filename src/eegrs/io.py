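"""HDF5 epoch containers and CSV metadata tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochTensor, ParticipantMeta, meta_frame

__all__ = ["save_epochs", "load_epochs", "save_meta", "load_meta", "cohort_dir"]


def save_epochs(epochs: EpochTensor, path: str | Path) -> None:
    """Write one participant's epochs: /data [s,p,channel,t], /kept, /channel_names."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=4)
        f.create_dataset("kept", data=epochs.kept)
        f.create_dataset(
            "channel_names",
            data=np.array(epochs.channel_names, dtype=h5py.string_dtype()),
        )
        f.attrs["sample_rate"] = epochs.sample_rate
        f.attrs["participant_id"] = epochs.participant_id


def load_epochs(path: str | Path) -> EpochTensor:
    with h5py.File(path, "r") as f:
        return EpochTensor(
            participant_id=f.attrs["participant_id"],
            data=f["data"][()],
            channel_names=[c.decode() if isinstance(c, bytes) else c for c in f["channel_names"][()]],
            sample_rate=float(f.attrs["sample_rate"]),
            kept=f["kept"][()],
        )


def save_meta(metas: list[ParticipantMeta], path: str | Path) -> None:
    meta_frame(metas).to_csv(path, index=False)


def load_meta(path: str | Path) -> list[ParticipantMeta]:
    df = pd.read_csv(path)
    return [
        ParticipantMeta(
            participant_id=str(r.participant_id), group=r.group, nviq=int(r.nviq),
            age=float(r.age), sex=r.sex, subgroup=r.subgroup,
        )
        for r in df.itertuples()
    ]


def cohort_dir(directory: str | Path) -> tuple[list[EpochTensor], list[ParticipantMeta]]:
    """Load every ``*.h5`` epoch file plus ``meta.csv`` from a directory."""
    directory = Path(directory)
    metas = load_meta(directory / "meta.csv")
    epochs = [load_epochs(p) for p in sorted(directory.glob("*.h5"))]
    ids = {e.participant_id for e in epochs}
    missing = [m.participant_id for m in metas if m.participant_id not in ids]
    if missing:
        raise FileNotFoundError(f"no epoch file for participants {missing}")
    return epochs, metas
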