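"""Spatial PCA: factor retention, Varimax properties, ROI assignment."""

import numpy as np
import pandas as pd
import pytest

from eegrs.montage import default_montage, gaussian_topographies, name_location
from eegrs.spatial import (SpatialFactorModel, build_observation_matrix,
                           derive_rois, factors_to_rois, spatial_pca, varimax)


def tucker(a, b):
    return abs(a @ b) / np.sqrt((a @ a) * (b @ b))


def planted_matrix(topos, scores_sd, noise_sd, n_obs=300, seed=0):
    """Observations = sum_j s_ij * topo_j + white noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, noise_sd, size=(n_obs, topos.shape[1]))
    for j, v in enumerate(topos):
        X += rng.normal(0, scores_sd[j], size=(n_obs, 1)) * v
    return X


def block_topos(sizes):
    n = sum(sizes)
    topos = np.zeros((len(sizes), n))
    off = 0
    for j, k in enumerate(sizes):
        topos[j, off:off + k] = 1.0 / np.sqrt(k)
        off += k
    return topos


def test_single_planted_topography_recovered():
    topo = block_topos([30])[0]
    X = planted_matrix(topo[None, :], scores_sd=[10.0], noise_sd=1.0, seed=1)
    model = spatial_pca(X)
    assert model.n_retained == 1
    assert tucker(model.loadings[:, 0], topo) > 0.99


def test_two_planted_topographies_recovered():
    topos = block_topos([15, 15])
    # variance shares ~45% / 35%: scores scaled so each source's total
    # variance fraction lands near the target against unit noise
    X = planted_matrix(topos, scores_sd=[11.0, 9.0], noise_sd=1.0, n_obs=500, seed=2)
    model = spatial_pca(X, cumulative_target=0.60)
    assert model.n_retained == 2
    congr = [max(tucker(model.loadings[:, k], topos[j]) for k in range(2)) for j in range(2)]
    assert min(congr) > 0.95


def test_varimax_preserves_communalities_and_variance():
    rng = np.random.default_rng(3)
    L = rng.normal(size=(40, 4))
    R_, rot = varimax(L)
    assert np.allclose(np.square(R_).sum(axis=1), np.square(L).sum(axis=1), atol=1e-8)
    assert np.allclose(np.square(R_).sum(), np.square(L).sum(), atol=1e-8)
    assert np.allclose(rot @ rot.T, np.eye(4), atol=1e-10)


def test_rotation_invariance_of_fit_on_planted_model():
    topos = block_topos([12, 10, 8])
    X = planted_matrix(topos, scores_sd=[8.0, 7.0, 6.0], noise_sd=1.0, seed=4)
    model = spatial_pca(X, cumulative_target=0.60)
    assert np.allclose(
        np.square(model.loadings).sum(), np.square(model.unrotated_loadings).sum(), atol=1e-8)


def test_channel_permutation_permutes_loadings():
    topos = block_topos([10, 10])
    X = planted_matrix(topos, scores_sd=[8.0, 6.0], noise_sd=1.0, seed=5)
    perm = np.random.default_rng(6).permutation(X.shape[1])
    m1 = spatial_pca(X)
    m2 = spatial_pca(X[:, perm])
    k = min(m1.n_retained, m2.n_retained)
    for j in range(k):
        congr = max(tucker(m2.loadings[:, j], m1.loadings[perm, i]) for i in range(k))
        assert congr > 0.999


def test_zero_variance_channel_named_in_error():
    X = np.random.default_rng(0).normal(size=(50, 4))
    X[:, 2] = 5.0
    with pytest.raises(ValueError, match="E3"):
        spatial_pca(X)


def test_build_observation_matrix_shapes():
    rng = np.random.default_rng(0)
    rows = []
    for g, pids in (("control", 3), ("fxs_low", 2), ("fxs_high", 2)):
        for i in range(pids):
            for s in range(1, 4):
                for p in range(1, 11):
                    for ch in ("E1", "E2"):
                        rows.append({"participant_id": f"{g}{i}", "subgroup": g,
                                     "stimulus": s, "presentation": p,
                                     "region": ch, "energy": rng.gamma(5.0)})
    tab = pd.DataFrame(rows)
    assert build_observation_matrix(tab, "control").shape == (30, 2)
    assert build_observation_matrix(tab, "fxs").shape == (40, 2)
    with pytest.raises(ValueError):
        build_observation_matrix(tab, "patients")


def _model_from_loadings(L, channels=None, group="g"):
    p, k = L.shape
    return SpatialFactorModel(
        group=group,
        channels=channels or [f"E{i + 1}" for i in range(p)],
        loadings=L, unrotated_loadings=L,
        variance_explained=np.full(p, 1.0 / p), n_retained=k, cumulative_target=0.6)


def test_identity_loadings_give_exact_planted_rois():
    L = np.zeros((10, 2))
    L[:5, 0] = 1.0
    L[5:, 1] = 1.0
    rois = factors_to_rois(_model_from_loadings(L), montage=default_montage(10))
    sets = {frozenset(r.channels) for r in rois}
    assert sets == {frozenset(f"E{i}" for i in range(1, 6)),
                    frozenset(f"E{i}" for i in range(6, 11))}


def test_loading_threshold_boundary():
    L = np.zeros((3, 1))
    L[0, 0] = 0.39   # below threshold: unassigned
    L[1, 0] = 0.40   # at threshold: kept
    L[2, 0] = 0.90
    rois = factors_to_rois(_model_from_loadings(L), loading_threshold=0.40,
                           montage=default_montage(3))
    assert sorted(rois.rois[0].channels) == ["E2", "E3"]
    with pytest.raises(ValueError):
        factors_to_rois(_model_from_loadings(np.full((3, 1), 0.1)),
                        montage=default_montage(3))


def test_roi_sets_disjoint_within_model():
    topos = block_topos([8, 8, 8])
    X = planted_matrix(topos, scores_sd=[8.0, 7.0, 6.0], noise_sd=1.0, seed=9)
    model = spatial_pca(X)
    rois = factors_to_rois(model, montage=default_montage(24))
    seen = set()
    for roi in rois:
        assert not (seen & set(roi.channels))
        seen |= set(roi.channels)


def test_name_location_regions():
    assert name_location(0.5, 0.6) == "frontal-right"
    assert name_location(0.0, 0.0) == "central"
    assert name_location(-0.8, -0.1) == "temporal-left"
    assert name_location(0.0, -0.7) == "occipital"


def test_gaussian_topographies_orthonormal():
    topo, names = gaussian_topographies(default_montage(99))
    assert topo.shape == (7, 99)
    assert np.allclose(topo @ topo.T, np.eye(7), atol=1e-10)


def test_study_scale_group_factor_structure(study_scale_run):
    """Structural analogue of the study's spatial factors: the control group
    retains five factors and the FXS group two at the 60% target, pooling to
    seven ROIs (disjoint within each group's factor model)."""
    table, metas, _ = study_scale_run
    rois, models = derive_rois(table)
    assert models["control"].n_retained == 5
    assert models["fxs"].n_retained == 2
    assert models["control"].cumulative_variance >= 0.60
    assert models["fxs"].cumulative_variance >= 0.60
    assert len(rois) == 7
    for group in ("control", "fxs"):
        seen = set()
        for roi in rois:
            if roi.source_group != group:
                continue
            assert not (seen & set(roi.channels))
            seen |= set(roi.channels)
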