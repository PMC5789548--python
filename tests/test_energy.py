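"""Normalized signal energy: defining identities and planted-effect recovery."""

import numpy as np
import pytest
from scipy import stats

from eegrs.containers import EpochTensor, ROI, ROISet
from eegrs.energy import (DegenerateSeriesError, compute_energy, energy_table,
                          normalize_repetition_series, participant_energy,
                          subtract_evoked)
from eegrs.simulate import generate_cohort

from conftest import small_config, two_block_rois, two_block_topographies


def tensor_from(data, kept=None):
    data = np.asarray(data, dtype=float)
    return EpochTensor("p1", data, [f"E{i + 1}" for i in range(data.shape[2])], 250.0, kept=kept)


# --- normalize_repetition_series -------------------------------------------

def test_normalization_hand_computed():
    # pooled samples 1,1,-1,-1: sample SD = sqrt(4/3), epochs scale to 0.8660
    series = np.array([[1.0, 1.0], [-1.0, -1.0]])
    out, rec = normalize_repetition_series(series)
    assert rec.sd_pooled == pytest.approx(np.sqrt(4.0 / 3.0), abs=1e-12)
    assert out[0] == pytest.approx([0.8660254, 0.8660254], abs=1e-6)


def test_normalization_unit_sd_identity_and_contract():
    rng = np.random.default_rng(0)
    series = rng.normal(size=(10, 20))
    series = (series - series.mean()) / series.std(ddof=1)  # already pooled SD 1
    out, _ = normalize_repetition_series(series)
    assert np.allclose(out, series, atol=1e-12)
    out2, _ = normalize_repetition_series(rng.normal(0, 7.0, size=(10, 20)))
    assert np.std(out2, ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_normalization_excludes_rejected_presentations():
    series = np.vstack([np.ones((1, 4)) * 1e6, np.random.default_rng(1).normal(size=(9, 4))])
    kept = np.ones(10, dtype=bool)
    kept[0] = False
    out, rec = normalize_repetition_series(series, kept=kept)
    assert np.isnan(out[0]).all()
    assert rec.sd_pooled < 10  # the 1e6 epoch did not inflate the divisor
    assert np.nanstd(out[1:], ddof=1) == pytest.approx(1.0, rel=1e-6)


def test_constant_series_degenerate():
    with pytest.raises(DegenerateSeriesError):
        normalize_repetition_series(np.ones((10, 5)))


# --- compute_energy ----------------------------------------------------------

def test_energy_direct_values():
    assert compute_energy(np.zeros(50)) == 0.0
    assert compute_energy(np.array([1.0, 2.0, -2.0])) == 9.0


def test_energy_additive_over_disjoint_windows():
    rng = np.random.default_rng(3)
    x = rng.normal(size=120)
    assert compute_energy(x) == pytest.approx(
        compute_energy(x[:50]) + compute_energy(x[50:]), rel=1e-12)


def test_energy_sum_identity_mean_zero_series():
    """Sum of per-presentation energies of a mean-zero normalized complete
    series equals 10*T - 1 (sample-SD normalization, ddof=1)."""
    rng = np.random.default_rng(11)
    T = 200
    series = rng.normal(size=(10, T))
    series -= series.mean()  # pooled mean zero
    out, _ = normalize_repetition_series(series)
    total = sum(compute_energy(out[p]) for p in range(10))
    assert total == pytest.approx(10 * T - 1, abs=1e-6)


# --- subtract_evoked ---------------------------------------------------------

def test_subtract_evoked_mode_none_identity():
    et = tensor_from(np.random.default_rng(0).normal(size=(3, 2, 2, 10)))
    assert subtract_evoked(et, mode="none") is et


def test_subtract_evoked_removes_identical_epochs():
    epoch = np.random.default_rng(1).normal(size=(2, 10))
    data = np.broadcast_to(epoch, (18, 1, 2, 10)).copy()
    out = subtract_evoked(tensor_from(data))
    assert np.max(np.abs(out.data)) < 1e-12


def test_subtract_evoked_requires_two_stimuli():
    et = tensor_from(np.zeros((1, 2, 2, 10)))
    with pytest.raises(ValueError):
        subtract_evoked(et)


def test_subtract_evoked_component_separation():
    """With the generator's stored truth: >= 80% of induced energy survives,
    <= 10% of evoked energy survives (18 stimuli, random-phase induced)."""
    cfg = small_config(seed=13, n_controls=4, n_fxs_low=1, n_fxs_high=1,
                      n_channels=4, n_samples=100, noise_sd=0.5,
                      topographies=two_block_topographies(4))
    cfg.store_components = True
    cohort, _ = generate_cohort(cfg)
    et = cohort[0]
    out = subtract_evoked(et)
    resid = out.data
    induced = et.components["induced"]
    evoked = et.components["evoked"]
    # energy of the residual projected on each true component
    e_induced_in = np.square(induced).sum()
    e_evoked_in = np.square(evoked).sum()
    e_induced_out = (resid * induced).sum() ** 2 / e_induced_in
    e_evoked_out = (resid * evoked).sum() ** 2 / e_evoked_in
    assert e_induced_out / e_induced_in >= 0.80
    assert e_evoked_out / e_evoked_in <= 0.10


# --- energy_table ------------------------------------------------------------

def test_scale_invariance_of_energy():
    cfg = small_config(seed=4, n_controls=2, n_fxs_low=1, n_fxs_high=1,
                      n_channels=4, n_samples=40, topographies=two_block_topographies(4))
    cohort, metas = generate_cohort(cfg)
    base = energy_table(cohort, metas)
    scaled = [c.with_data(c.data * 3.7) for c in cohort]
    tab2 = energy_table(scaled, metas)
    assert np.allclose(base["energy"], tab2["energy"], atol=1e-9)


def test_energy_table_row_count_seven_rois():
    cfg = small_config(seed=8, n_channels=14, n_samples=30,
                      topographies=two_block_topographies(14))
    cohort, metas = generate_cohort(cfg)
    rois = ROISet([ROI(f"R{j + 1}", [f"E{2 * j + 1}", f"E{2 * j + 2}"], "sim", j + 1)
                   for j in range(7)])
    tab = energy_table(cohort, metas, rois=rois)
    assert len(tab) == 40 * 18 * 10 * 7  # 50,400 rows, no rejections
    assert (tab["energy"] >= 0).all()


def test_energy_table_unknown_roi_channel():
    cfg = small_config(seed=8, n_controls=1, n_fxs_low=1, n_fxs_high=1,
                      n_channels=4, n_samples=20, topographies=two_block_topographies(4))
    cohort, metas = generate_cohort(cfg)
    rois = ROISet([ROI("bad", ["E99"], "sim", 1)])
    with pytest.raises(KeyError):
        energy_table(cohort, metas, rois=rois)


def test_rejected_epochs_absent_from_table():
    cfg = small_config(seed=14, n_controls=1, n_fxs_low=1, n_fxs_high=1,
                      n_channels=4, n_samples=20, topographies=two_block_topographies(4))
    cohort, metas = generate_cohort(cfg)
    et = cohort[0]
    et.kept[0, 0] = False
    et.kept[5, 9] = False
    tab = energy_table(cohort, metas)
    sub = tab[tab.participant_id == et.participant_id]
    assert len(sub) == (180 - 2) * 4
    assert sub[(sub.stimulus == 1) & (sub.presentation == 1)].empty


def test_control_group_mean_energy_drop_p1_p2():
    """Planted control habituation: group-mean E at P1 exceeds P2."""
    tab, metas = _control_table(seed=31, n_controls=20)
    m = tab.groupby("presentation").energy.mean()
    per_part = tab[tab.presentation.isin([1, 2])].pivot_table(
        index="participant_id", columns="presentation", values="energy")
    t, p = stats.ttest_rel(per_part[1], per_part[2], alternative="greater")
    assert m[1] > m[2]
    assert p < 0.01


def test_null_profile_energy_flat_across_presentations():
    """Flat gain profiles: regression slope of mean E on presentation has a
    confidence interval containing zero (>= 100 participants)."""
    tab, _ = _control_table(seed=32, n_controls=100, null=True)
    per = tab.groupby(["participant_id", "presentation"]).energy.mean().reset_index()
    res = stats.linregress(per["presentation"], per["energy"])
    ci = 1.96 * res.stderr
    assert abs(res.slope) < ci + 1e-12


def test_mean_energy_scale_band_small():
    """Unit-variance normalization pins per-presentation mean energy near T
    (flat-profile cohort, where no planted modulation shifts the scale)."""
    tab, _ = _control_table(seed=33, n_controls=10, null=True)
    T = 50
    per_p = tab.groupby("presentation").energy.mean()
    assert ((per_p >= 0.8 * T) & (per_p <= 1.2 * T)).all()


def _control_table(seed, n_controls, null=False):
    cfg = small_config(seed, null=null, n_controls=n_controls, n_fxs_low=1, n_fxs_high=1)
    cohort, metas = generate_cohort(cfg)
    keep = {m.participant_id for m in metas if m.subgroup == "control"}
    cohort = [c for c in cohort if c.participant_id in keep]
    metas = [m for m in metas if m.participant_id in keep]
    return energy_table(cohort, metas, rois=two_block_rois()), metas
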