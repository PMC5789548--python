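"""Data-driven ROI derivation via spatial PCA with Varimax rotation.

For each participant group, channel-level energies are averaged over stimuli
to an observation matrix with one row per (participant, presentation) and one
column per channel.  A correlation-matrix PCA retains the smallest leading
factor set whose cumulative explained variance reaches the target (default
60%), Varimax-rotates the retained loadings, and assigns each channel to the
factor on which its absolute rotated loading is maximal, provided that
loading reaches the salience threshold (default 0.40, the conventional
cutoff).  Each surviving factor becomes a named ROI; the name comes from the
scalp centroid of its channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ROI, ROISet
from .montage import default_montage, name_location

__all__ = [
    "build_observation_matrix",
    "spatial_pca",
    "varimax",
    "factors_to_rois",
    "derive_rois",
    "SpatialFactorModel",
]


def build_observation_matrix(energy: pd.DataFrame, group: str) -> pd.DataFrame:
    """(participants x presentations) by channels matrix of stimulus-averaged energy.

    ``energy`` must be a channel-level energy table; ``group`` is ``'control'``
    or ``'fxs'`` (the latter pools both NVIQ subgroups).
    """
    if group == "control":
        sub = energy[energy["subgroup"] == "control"]
    elif group == "fxs":
        sub = energy[energy["subgroup"].isin(["fxs_low", "fxs_high"])]
    else:
        raise ValueError(f"group must be 'control' or 'fxs', got {group!r}")
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    mat = (
        sub.groupby(["participant_id", "presentation", "region"], sort=True)["energy"]
        .mean()
        .unstack("region")
    )
    if mat.isna().any().any():
        missing = mat.columns[mat.isna().any()].tolist()
        raise ValueError(f"missing channel energies for columns {missing}")
    return mat


@dataclass
class SpatialFactorModel:
    group: str
    channels: list[str]
    loadings: np.ndarray            # (n_channels, n_retained), Varimax-rotated
    unrotated_loadings: np.ndarray  # (n_channels, n_retained)
    variance_explained: np.ndarray  # per-factor proportion, pre-rotation order
    n_retained: int
    cumulative_target: float

    @property
    def cumulative_variance(self) -> float:
        return float(self.variance_explained[: self.n_retained].sum())

    @property
    def communalities(self) -> np.ndarray:
        return np.square(self.loadings).sum(axis=1)


def varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Raw Varimax rotation; returns (rotated loadings, rotation matrix).

    Iterative SVD algorithm maximizing the variance of squared loadings per
    factor.  Orthogonal: communalities are invariant.  Sign convention: each
    rotated factor is flipped so its largest-magnitude loading is positive.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    R = np.eye(k)
    if k < 2:
        rotated = L.copy()
    else:
        d = 0.0
        for _ in range(max_iter):
            Lr = L @ R
            grad = L.T @ (Lr**3 - Lr @ np.diag(np.square(Lr).sum(axis=0)) / p)
            u, s, vt = np.linalg.svd(grad)
            R = u @ vt
            d_new = s.sum()
            if d_new <= d * (1 + tol):
                break
            d = d_new
        rotated = L @ R
    signs = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(rotated.shape[1])])
    signs[signs == 0] = 1.0
    return rotated * signs, R * signs


def spatial_pca(matrix: pd.DataFrame | np.ndarray, cumulative_target: float = 0.60,
                group: str = "") -> SpatialFactorModel:
    """Correlation-matrix PCA with Varimax rotation of the retained factors."""
    if isinstance(matrix, pd.DataFrame):
        channels = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        channels = [f"E{i + 1}" for i in range(X.shape[1])]
    n, c = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = X.std(axis=0, ddof=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance channels: {[channels[i] for i in dead]}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    props = eigval / c
    cum = np.cumsum(props)
    n_retained = int(np.searchsorted(cum, cumulative_target - 1e-12) + 1)
    n_retained = min(n_retained, c)
    unrotated = eigvec[:, :n_retained] * np.sqrt(eigval[:n_retained])
    rotated, _ = varimax(unrotated)
    return SpatialFactorModel(
        group=group,
        channels=channels,
        loadings=rotated,
        unrotated_loadings=unrotated,
        variance_explained=props,
        n_retained=n_retained,
        cumulative_target=cumulative_target,
    )


def factors_to_rois(model: SpatialFactorModel, loading_threshold: float = 0.40,
                    montage: pd.DataFrame | None = None) -> ROISet:
    """Max-loading channel assignment with a salience threshold.

    A channel joins the factor on which its absolute rotated loading is
    maximal iff that loading is >= ``loading_threshold``; factors that end up
    with no channels are dropped.  ROIs are named from the scalp centroid of
    their channels (with the factor index as a tiebreaker for duplicates).
    """
    L = model.loadings
    if L.shape[1] == 0:
        raise ValueError("model has no retained factors")
    if montage is None:
        montage = default_montage(len(model.channels))
    pos = montage.set_index("channel")
    best = np.argmax(np.abs(L), axis=1)
    strength = np.abs(L)[np.arange(L.shape[0]), best]
    rois = []
    for j in range(L.shape[1]):
        members = [model.channels[i] for i in range(L.shape[0])
                   if best[i] == j and strength[i] >= loading_threshold]
        if not members:
            continue
        xy = pos.loc[members, ["x", "y"]].mean()
        rois.append(ROI(
            name=name_location(float(xy["x"]), float(xy["y"])),
            channels=members,
            source_group=model.group,
            factor_index=j + 1,
        ))
    if not rois:
        raise ValueError("no channel reached the loading threshold on any factor")
    # disambiguate duplicate names within the model
    seen: dict[str, int] = {}
    for roi in rois:
        seen[roi.name] = seen.get(roi.name, 0) + 1
    counts: dict[str, int] = {}
    for roi in rois:
        if seen[roi.name] > 1:
            counts[roi.name] = counts.get(roi.name, 0) + 1
            roi.name = f"{roi.name}-f{roi.factor_index}"
    return ROISet(rois)


def derive_rois(energy: pd.DataFrame, cumulative_target: float = 0.60,
                loading_threshold: float = 0.40,
                montage: pd.DataFrame | None = None,
                groups: tuple[str, ...] = ("fxs", "control")) -> tuple[ROISet, dict[str, SpatialFactorModel]]:
    """Per-group spatial PCA pooled into a single ROI set for all participants.

    The combined set keeps each group's factor-derived ROIs side by side
    (duplicate names across groups are suffixed with the source group), the
    way the downstream model and decoding stages use one shared ROI set.
    ROIs are disjoint within a group's factor model; across groups they may
    overlap, since each group's factors partition the montage independently.
    """
    all_rois: list[ROI] = []
    models: dict[str, SpatialFactorModel] = {}
    seen_sets: dict[frozenset, ROI] = {}
    for group in groups:
        mat = build_observation_matrix(energy, group)
        model = spatial_pca(mat, cumulative_target=cumulative_target, group=group)
        models[group] = model
        for roi in factors_to_rois(model, loading_threshold, montage):
            key = frozenset(roi.channels)
            if key in seen_sets:
                # both groups derived the same electrode set: one region
                seen_sets[key].source_group += f"+{group}"
                continue
            seen_sets[key] = roi
            all_rois.append(roi)
    names: dict[str, int] = {}
    for roi in all_rois:
        names[roi.name] = names.get(roi.name, 0) + 1
    for roi in all_rois:
        if names[roi.name] > 1:
            roi.name = f"{roi.name} ({roi.source_group})"
    return ROISet(all_rois), models
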