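"""Single-trial decoding of NVIQ subgroups from repetition-suppression features.

Features are single-trial energy drops: for each ROI, ``E(P1) - E(Pj)`` for
j = 2..10 and ``E(P2) - E(Pj)`` for j = 3..10 (17 per ROI; 119 for 7 ROIs).
One trial = one (participant, pseudoword) pair, so 14 FXS participants with
complete data give 252 rows.

Classification uses leave-two-subject-out cross-validation on bootstrap-
balanced classes: every subset of the larger class with the size of the
smaller class is enumerated (C(8,6) = 28 subsets of 216 trials), and within
each balanced subset every cross-class participant pair serves once as the
test fold (6 x 6 = 36 folds; train = the other 10 participants' 180 trials,
test = the pair's 36 trials).  Per feature, an RBF-kernel SVM is fit per fold
on z-scored values (statistics from the training trials only); the decoding
accuracy (DA) of a subset is its mean fold accuracy, the reported mean DA is
the mean over subsets and the s.e.m. is taken across subsets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from sklearn.svm import SVC

from .containers import ParticipantMeta, meta_frame

__all__ = [
    "build_rs_features",
    "make_fold_plan",
    "decode_feature",
    "run_decoding",
    "feature_pairs",
    "RSFeatureMatrix",
    "FoldPlan",
]

CLASS_LABELS = ("fxs_low", "fxs_high")


def feature_pairs(n_presentations: int = 10) -> list[tuple[int, int]]:
    """Presentation pairs (i, j) defining the RS features, in column order."""
    pairs = [(1, j) for j in range(2, n_presentations + 1)]
    pairs += [(2, j) for j in range(3, n_presentations + 1)]
    return pairs


@dataclass
class RSFeatureMatrix:
    """Trial-by-feature matrix with class labels and participant ids."""

    X: pd.DataFrame               # rows: (participant, stimulus); columns: "<roi> <i>-<j>"
    labels: np.ndarray            # subgroup per row
    participants: np.ndarray      # participant id per row
    roi_order: list[str]

    def __post_init__(self):
        if not (len(self.X) == len(self.labels) == len(self.participants)):
            raise ValueError("inconsistent row counts")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def build_rs_features(
    energy: pd.DataFrame,
    metas: list[ParticipantMeta] | pd.DataFrame,
    roi_order: list[str] | None = None,
) -> RSFeatureMatrix:
    """Energy-difference features for all FXS trials from an ROI-level table.

    Column order: ROIs in ``roi_order`` (default: sorted), within each ROI the
    pairs ``1-2 .. 1-10, 2-3 .. 2-10``.  A trial with a rejected constituent
    presentation gets NaN in the affected features; downstream folds drop
    NaN rows per feature.
    """
    meta = metas if isinstance(metas, pd.DataFrame) else meta_frame(metas)
    fxs = meta[meta["subgroup"].isin(CLASS_LABELS)]
    sub = energy[energy["participant_id"].isin(fxs["participant_id"])]
    if sub.empty:
        raise ValueError("no FXS rows in energy table")
    rois = sorted(sub["region"].unique()) if roi_order is None else list(roi_order)
    missing = set(rois) - set(sub["region"].unique())
    if missing:
        raise KeyError(f"ROIs missing from energy table: {sorted(missing)}")
    n_pres = int(energy["presentation"].max())
    wide = sub.pivot_table(
        index=["participant_id", "stimulus"],
        columns=["region", "presentation"],
        values="energy",
        aggfunc="first",
    )
    cols = {}
    for roi in rois:
        for i, j in feature_pairs(n_pres):
            ei = wide[(roi, i)] if (roi, i) in wide.columns else np.nan
            ej = wide[(roi, j)] if (roi, j) in wide.columns else np.nan
            cols[f"{roi} {i}-{j}"] = ei - ej
    X = pd.DataFrame(cols, index=wide.index)
    label_of = dict(zip(fxs["participant_id"], fxs["subgroup"]))
    pids = X.index.get_level_values("participant_id").to_numpy()
    labels = np.array([label_of[p] for p in pids])
    return RSFeatureMatrix(X=X, labels=labels, participants=pids, roi_order=rois)


@dataclass
class FoldPlan:
    """Bootstrap-balanced leave-two-subject-out fold layout."""

    subsets: list[tuple]                   # balanced subsets of the larger class
    folds: list[list[tuple]]               # per subset: (test_pair, train_ids)
    class_a: tuple                         # larger class participant ids
    class_b: tuple                         # smaller class participant ids
    field_names: tuple = field(default=("test", "train"), repr=False)

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)


def make_fold_plan(meta: list[ParticipantMeta] | pd.DataFrame) -> FoldPlan:
    """Enumerate all balanced subsets and cross-class test pairs.

    With class sizes (8, 6) this yields C(8,6) = 28 subsets, each with
    6 x 6 = 36 folds whose test sets are one participant per class.
    """
    frame = meta if isinstance(meta, pd.DataFrame) else meta_frame(meta)
    low = tuple(sorted(frame.loc[frame["subgroup"] == "fxs_low", "participant_id"]))
    high = tuple(sorted(frame.loc[frame["subgroup"] == "fxs_high", "participant_id"]))
    if min(len(low), len(high)) < 2:
        raise ValueError("each class needs at least 2 participants")
    big, small = (low, high) if len(low) >= len(high) else (high, low)
    subsets = list(itertools.combinations(big, len(small)))
    folds = []
    for subset in subsets:
        fold_list = []
        for a in subset:
            for b in small:
                train = tuple(x for x in subset if x != a) + tuple(x for x in small if x != b)
                fold_list.append(((a, b), train))
        folds.append(fold_list)
    return FoldPlan(subsets=subsets, folds=folds, class_a=big, class_b=small)


def _fold_accuracy(x, y, participants, test_pair, train_ids, clf_kwargs):
    train_mask = np.isin(participants, train_ids) & np.isfinite(x)
    test_mask = np.isin(participants, test_pair) & np.isfinite(x)
    if not test_mask.any():
        return np.nan
    y_train = y[train_mask]
    if len(np.unique(y_train)) < 2:
        return np.nan  # degenerate training labels; fold skipped
    mu = x[train_mask].mean()
    sd = x[train_mask].std()
    if sd == 0:
        sd = 1.0
    xt = ((x - mu) / sd)[:, None]
    clf = SVC(**clf_kwargs)
    clf.fit(xt[train_mask], y_train)
    return float(np.mean(clf.predict(xt[test_mask]) == y[test_mask]))


def decode_feature(
    values: np.ndarray,
    labels: np.ndarray,
    participants: np.ndarray,
    plan: FoldPlan,
    C: float = 1.0,
    gamma: str | float = "scale",
) -> dict:
    """Mean decoding accuracy of one feature under the fold plan.

    Returns mean DA and s.e.m. in percent, the per-subset DA vector and the
    number of skipped (degenerate) folds.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    clf_kwargs = {"C": C, "kernel": "rbf", "gamma": gamma}
    subset_das = []
    skipped = 0
    with sklearn.config_context(assume_finite=True):
        for fold_list in plan.folds:
            accs = []
            for test_pair, train_ids in fold_list:
                acc = _fold_accuracy(x, y, participants, test_pair, train_ids, clf_kwargs)
                if np.isnan(acc):
                    skipped += 1
                else:
                    accs.append(acc)
            subset_das.append(np.mean(accs) if accs else np.nan)
    subset_das = np.asarray(subset_das, dtype=float)
    mean_da = 100.0 * float(np.nanmean(subset_das))
    n_eff = int(np.sum(np.isfinite(subset_das)))
    sem = 100.0 * float(np.nanstd(subset_das, ddof=1) / np.sqrt(n_eff)) if n_eff > 1 else np.nan
    return {
        "mean_da": mean_da,
        "sem": sem,
        "subset_das": 100.0 * subset_das,
        "n_skipped_folds": skipped,
    }


def run_decoding(
    matrix: RSFeatureMatrix,
    plan: FoldPlan | None = None,
    C: float = 1.0,
    gamma: str | float = "scale",
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature decoding accuracies over the full (or selected) feature set.

    Returns a frame with one row per feature in documented column order:
    ``feature, roi, pair, mean_da, sem, n_skipped_folds`` plus per-subset DA
    columns ``subset_00 ..``.  Deterministic: the SVM fit and the exhaustive
    fold enumeration involve no randomness.
    """
    if plan is None:
        frame = pd.DataFrame({"participant_id": matrix.participants, "subgroup": matrix.labels}) \
            .drop_duplicates()
        plan = make_fold_plan(frame)
    names = list(matrix.X.columns) if features is None else list(features)
    rows = []
    for name in names:
        res = decode_feature(matrix.X[name].to_numpy(), matrix.labels,
                             matrix.participants, plan, C=C, gamma=gamma)
        roi, pair = name.rsplit(" ", 1)
        row = {"feature": name, "roi": roi, "pair": pair,
               "mean_da": res["mean_da"], "sem": res["sem"],
               "n_skipped_folds": res["n_skipped_folds"]}
        row.update({f"subset_{i:02d}": v for i, v in enumerate(res["subset_das"])})
        rows.append(row)
    return pd.DataFrame(rows)
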