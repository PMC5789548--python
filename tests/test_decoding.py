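"""Single-trial decoding: features, fold hygiene, SVM accuracy properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eegrs.containers import meta_frame
from eegrs.decoding import (build_rs_features, decode_feature, feature_pairs,
                            make_fold_plan, run_decoding)
from eegrs.energy import energy_table
from eegrs.simulate import generate_cohort

from conftest import fxs_only, small_config, two_block_rois

ROIS7 = ["C", "FL", "TL", "FC", "FR", "TR", "O"]


def synthetic_meta(n_low=8, n_high=6):
    return pd.DataFrame({
        "participant_id": [f"L{i}" for i in range(n_low)] + [f"H{i}" for i in range(n_high)],
        "subgroup": ["fxs_low"] * n_low + ["fxs_high"] * n_high,
    })


def synthetic_energy(meta, rois=ROIS7, n_stimuli=18, seed=0, constant=None):
    rng = np.random.default_rng(seed)
    rows = []
    for pid, sub in zip(meta["participant_id"], meta["subgroup"]):
        for s in range(1, n_stimuli + 1):
            for roi in rois:
                for p in range(1, 11):
                    e = constant if constant is not None else rng.gamma(50.0, 4.0)
                    rows.append({"participant_id": pid, "subgroup": sub, "stimulus": s,
                                 "presentation": p, "region": roi, "energy": e})
    return pd.DataFrame(rows)


def test_feature_pairs_order_and_count():
    pairs = feature_pairs(10)
    assert len(pairs) == 17
    assert pairs[0] == (1, 2) and pairs[8] == (1, 10)
    assert pairs[9] == (2, 3) and pairs[-1] == (2, 10)


def test_feature_matrix_dimensions():
    meta = synthetic_meta()
    fm = build_rs_features(synthetic_energy(meta), meta, roi_order=ROIS7)
    assert fm.X.shape == (252, 119)  # 14 participants x 18 trials, 17 x 7 features
    assert list(fm.X.columns[:2]) == ["C 1-2", "C 1-3"]
    assert fm.X.columns[17] == "FL 1-2"
    assert set(fm.labels) == {"fxs_low", "fxs_high"}


def test_feature_values_from_printed_energy_means():
    # per-presentation mean energies of the control column of the study's
    # summary table used as single-trial inputs: P1 = 213.2, P2 = 192.2
    meta = synthetic_meta(1, 1)
    tab = synthetic_energy(meta, rois=["FR"], n_stimuli=1, constant=0.0)
    values = {1: 213.2, 2: 192.2}
    tab["energy"] = [values.get(p, 200.0) for p in tab["presentation"]]
    fm = build_rs_features(tab, meta, roi_order=["FR"])
    assert fm.X.loc[:, "FR 1-2"].iloc[0] == pytest.approx(21.0, abs=1e-9)


def test_constant_energy_gives_zero_features():
    meta = synthetic_meta(2, 2)
    fm = build_rs_features(synthetic_energy(meta, constant=123.4), meta, roi_order=ROIS7)
    assert np.allclose(fm.X.to_numpy(), 0.0)


def test_missing_roi_raises():
    meta = synthetic_meta(2, 2)
    with pytest.raises(KeyError):
        build_rs_features(synthetic_energy(meta), meta, roi_order=ROIS7 + ["nope"])


def test_fold_plan_design_counts():
    plan = make_fold_plan(synthetic_meta())
    assert plan.n_subsets == 28                      # C(8, 6)
    for subset, folds in zip(plan.subsets, plan.folds):
        assert len(subset) == 6
        assert len(folds) == 36                      # 6 x 6 cross-class pairs
        for (a, b), train in folds:
            assert len(train) == 10


def test_fold_plan_no_subject_leakage():
    plan = make_fold_plan(synthetic_meta())
    for folds in plan.folds:
        for test_pair, train in folds:
            assert not (set(test_pair) & set(train))


def test_fold_plan_small_class_rejected():
    with pytest.raises(ValueError):
        make_fold_plan(synthetic_meta(8, 1))


def test_perfectly_separated_feature_decodes_100():
    meta = synthetic_meta(4, 3)
    rng = np.random.default_rng(0)
    pids, labels, vals = [], [], []
    for pid, sub in zip(meta["participant_id"], meta["subgroup"]):
        x = rng.uniform(-2, -1, 18) if sub == "fxs_low" else rng.uniform(1, 2, 18)
        vals.append(x)
        pids += [pid] * 18
        labels += [sub] * 18
    res = decode_feature(np.concatenate(vals), np.array(labels), np.array(pids),
                         make_fold_plan(meta))
    assert res["mean_da"] == pytest.approx(100.0)


def test_all_zero_feature_decodes_at_chance():
    meta = synthetic_meta(4, 3)
    n = len(meta) * 18
    pids = np.repeat(meta["participant_id"].to_numpy(), 18)
    labels = np.repeat(meta["subgroup"].to_numpy(), 18)
    res = decode_feature(np.zeros(n), labels, pids, make_fold_plan(meta))
    assert res["mean_da"] == pytest.approx(50.0)


def test_da_invariant_under_affine_feature_transform():
    meta = synthetic_meta(5, 4)
    rng = np.random.default_rng(3)
    pids = np.repeat(meta["participant_id"].to_numpy(), 18)
    labels = np.repeat(meta["subgroup"].to_numpy(), 18)
    x = rng.normal(size=len(pids)) + (labels == "fxs_high") * 0.8
    plan = make_fold_plan(meta)
    base = decode_feature(x, labels, pids, plan)
    moved = decode_feature(3.5 * x - 11.0, labels, pids, plan)
    assert moved["mean_da"] == pytest.approx(base["mean_da"], abs=1e-9)
    assert np.allclose(moved["subset_das"], base["subset_das"], atol=1e-9)


def test_label_permutation_null_near_chance():
    """Grand-mean DA over label permutations stays inside the 95% binomial
    band around 50% for the per-subset trial count."""
    meta = synthetic_meta(5, 4)
    rng = np.random.default_rng(4)
    pids = np.repeat(meta["participant_id"].to_numpy(), 18)
    x = rng.normal(size=len(pids))
    plan = make_fold_plan(meta)
    das = []
    for s in range(10):
        perm_labels = np.repeat(
            np.random.default_rng(100 + s).permutation(meta["subgroup"].to_numpy()), 18)
        plan_s = make_fold_plan(pd.DataFrame({
            "participant_id": meta["participant_id"],
            "subgroup": perm_labels[::18]}))
        das.append(decode_feature(x, perm_labels, pids, plan_s)["mean_da"])
    n_eval = 4 * 2 * 18  # balanced subset size per evaluation
    half_width = 100 * 1.96 * np.sqrt(0.25 / n_eval)
    assert abs(np.mean(das) - 50.0) < half_width


def test_nan_trials_dropped_and_folds_logged():
    meta = synthetic_meta(4, 3)
    pids = np.repeat(meta["participant_id"].to_numpy(), 18)
    labels = np.repeat(meta["subgroup"].to_numpy(), 18)
    x = np.random.default_rng(5).normal(size=len(pids))
    x[labels == "fxs_high"] += 5.0
    x[::7] = np.nan
    res = decode_feature(x, labels, pids, make_fold_plan(meta))
    assert np.isfinite(res["mean_da"])
    assert res["mean_da"] > 90.0


def test_top_ranked_features_match_planted_roi():
    """A subgroup difference planted in one source's early presentations puts
    that ROI's P1/P2-versus-early features at the top of the ranking."""
    h = 1.8
    early = np.ones(10)
    early[:3] = h
    flat = np.ones(10)
    sp = {"fxs_low": np.stack([flat, flat]), "fxs_high": np.stack([early, flat])}
    cfg = small_config(seed=61, n_controls=1, source_rs_profiles=sp)
    cohort, metas = fxs_only(*generate_cohort(cfg))
    tab = energy_table(cohort, metas, rois=two_block_rois())
    fm = build_rs_features(tab, metas, roi_order=["roiA", "roiB"])
    plan = make_fold_plan(meta_frame(metas))
    # "1-2" spans no gain step (presentations 1 and 2 share the elevated
    # gain), so it is a within-ROI null; roiB features are cross-ROI nulls
    probe = ["roiA 1-4", "roiA 2-4", "roiA 1-2", "roiB 1-4", "roiB 2-4", "roiB 1-2"]
    res = run_decoding(fm, plan, features=probe)
    best = res.loc[res["mean_da"].idxmax(), "feature"]
    assert best in ("roiA 1-4", "roiA 2-4")
    da = res.set_index("feature")["mean_da"]
    assert da["roiA 1-4"] > da["roiB 1-4"]
    assert da["roiA 1-4"] > da["roiA 1-2"]


def test_run_decoding_deterministic():
    meta = synthetic_meta(3, 3)
    tab = synthetic_energy(meta, rois=["C"], seed=8)
    fm = build_rs_features(tab, meta, roi_order=["C"])
    plan = make_fold_plan(meta)
    r1 = run_decoding(fm, plan, features=["C 1-2"])
    r2 = run_decoding(fm, plan, features=["C 1-2"])
    pd.testing.assert_frame_equal(r1, r2)
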