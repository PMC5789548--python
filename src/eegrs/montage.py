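"""Synthetic dense-array scalp montage.

The study montage (a 128-electrode geodesic net with 30 neck/face channels
removed, leaving 99) is not distributed with coordinates, so the package
generates a deterministic stand-in: channels on concentric rings of a unit
disk in a top-down 2-D projection, nose pointing to +y.  Coordinates are only
used for (a) placing spatially contiguous planted sources in the simulator and
(b) naming data-driven ROIs by scalp location; no forward modeling depends on
them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# canonical scalp region seeds (x, y) in the unit-disk projection, ordered to
# match the simulator's default source list: the first two are the regions the
# FXS factor structure concentrates in, the last five the control regions.
REGION_SEEDS = {
    "central": (0.0, 0.0),
    "frontal-left": (-0.45, 0.6),
    "temporal-left": (-0.8, -0.05),
    "fronto-central": (0.0, 0.42),
    "frontal-right": (0.45, 0.6),
    "temporal-right": (0.8, -0.05),
    "occipital": (0.0, -0.72),
}


def default_montage(n_channels: int = 99) -> pd.DataFrame:
    """Deterministic 2-D layout with columns (channel, x, y).

    Channels are labeled ``E1..En`` and placed on concentric rings with counts
    proportional to ring circumference, mimicking a dense geodesic array.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    # ring radii and per-ring counts; inner rings sparse, outer rings dense
    n_rings = max(2, int(np.ceil(np.sqrt(n_channels) / 1.6)) + 2)
    radii = np.linspace(0.0, 0.95, n_rings)
    weights = np.maximum(radii, 0.12)
    counts = np.maximum(1, np.round(weights / weights.sum() * n_channels).astype(int))
    # adjust rounding so the total matches exactly
    while counts.sum() > n_channels:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_channels:
        counts[np.argmax(radii)] += 1
    xs, ys = [], []
    for k, (r, c) in enumerate(zip(radii, counts)):
        theta = 2 * np.pi * (np.arange(c) + 0.5 * (k % 2)) / c + np.pi / 2
        xs.extend(r * np.cos(theta))
        ys.extend(r * np.sin(theta))
    return pd.DataFrame(
        {
            "channel": [f"E{i + 1}" for i in range(n_channels)],
            "x": np.asarray(xs)[:n_channels],
            "y": np.asarray(ys)[:n_channels],
        }
    )


def partition_regions(montage: pd.DataFrame, regions: list[str] | None = None) -> dict[str, list[str]]:
    """Assign every channel to its nearest region seed (contiguous partition)."""
    regions = list(REGION_SEEDS) if regions is None else list(regions)
    seeds = np.array([REGION_SEEDS[r] for r in regions])
    pts = montage[["x", "y"]].to_numpy()
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    out: dict[str, list[str]] = {r: [] for r in regions}
    for ch, i in zip(montage["channel"], idx):
        out[regions[i]].append(ch)
    empty = [r for r, chs in out.items() if not chs]
    if empty:
        raise ValueError(f"region partition produced empty regions: {empty}")
    return out


def region_topographies(montage: pd.DataFrame, regions: list[str] | None = None,
                        zero_sum: bool = True) -> tuple[np.ndarray, list[str]]:
    """Unit-norm region topographies, one per region (mutually orthogonal).

    Each pattern lives on the channels of one contiguous region.  With
    ``zero_sum=True`` (the default) it is a center-surround (dipolar)
    pattern: positive over the half of the region closest to the seed,
    negative over the surrounding half, scaled so the channel sum is zero.
    Zero-sum patterns are exactly what average-referenced data supports, so
    re-referencing leaves the planted sources untouched, and the disjoint
    supports make the patterns exactly orthogonal with no cross-region
    leakage.  Returns ``(topographies, region_names)`` with shape
    ``(n_regions, n_channels)`` in montage channel order.
    """
    part = partition_regions(montage, regions)
    chan_index = {ch: i for i, ch in enumerate(montage["channel"])}
    pos = montage.set_index("channel")
    topo = np.zeros((len(part), len(chan_index)))
    for j, (name, chans) in enumerate(part.items()):
        if zero_sum and len(chans) >= 2:
            sx, sy = REGION_SEEDS[name]
            d = {ch: (pos.at[ch, "x"] - sx) ** 2 + (pos.at[ch, "y"] - sy) ** 2 for ch in chans}
            ordered = sorted(chans, key=d.get)
            n_core = max(1, len(chans) // 2)
            core, ring = ordered[:n_core], ordered[n_core:]
            for ch in core:
                topo[j, chan_index[ch]] = 1.0
            for ch in ring:
                topo[j, chan_index[ch]] = -len(core) / len(ring)
        else:
            for ch in chans:
                topo[j, chan_index[ch]] = 1.0
        topo[j] /= np.linalg.norm(topo[j])
    return topo, list(part)


def gaussian_topographies(
    montage: pd.DataFrame,
    regions: list[str] | None = None,
    width: float = 0.7,
) -> tuple[np.ndarray, list[str]]:
    """Broad, mutually orthogonal scalp patterns centered on region seeds.

    Gaussian bumps of spatial scale ``width`` (unit-disk coordinates) are
    orthonormalized by Gram-Schmidt in region order.  Unlike the disjoint
    indicator topographies, these overlap and span most of the scalp, the way
    volume-conducted source patterns do in real recordings, so a small number
    of sources can carry the bulk of the between-channel covariance.
    """
    regions = list(REGION_SEEDS) if regions is None else list(regions)
    pts = montage[["x", "y"]].to_numpy()
    out = []
    for name in regions:
        cx, cy = REGION_SEEDS[name]
        v = np.exp(-((pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2) / (2 * width**2))
        for q in out:
            v = v - (v @ q) * q
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise ValueError(f"region {name!r} pattern collapsed during orthogonalization")
        out.append(v / norm)
    return np.array(out), regions


def name_location(x: float, y: float) -> str:
    """Human-readable scalp location name for a centroid in the 2-D layout."""
    if y > 0.5:
        region = "frontal"
    elif y > 0.18:
        region = "fronto-central"
    elif y > -0.3:
        region = "central" if abs(x) < 0.45 else "temporal"
    elif y > -0.55:
        region = "parietal"
    else:
        region = "occipital"
    if x < -0.2:
        side = "-left"
    elif x > 0.2:
        side = "-right"
    else:
        side = ""
    return region + side
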