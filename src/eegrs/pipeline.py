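"""End-to-end orchestration: simulate -> preprocess -> energy -> ROIs ->
mixed-model ladder -> decoding -> significance, with a reproducibility
manifest.

Every run writes tidy CSV/JSON artifacts plus ``manifest.json`` recording the
configuration hash, package versions, master seed and per-stage row counts;
deterministic stages reproduce bit-identically under the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import meta_frame
from .decoding import build_rs_features, make_fold_plan, run_decoding
from .energy import energy_table
from .io import save_epochs, save_meta
from .lmm import run_ladder
from .preprocess import preprocess_cohort
from .significance import SignificanceSpec, flag_significant
from .simulate import SimConfig, generate_cohort
from .spatial import derive_rois

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "preprocess", "energy", "rois", "lmm", "decode", "signif")


@dataclass
class PipelineConfig:
    out_dir: str = "eegrs_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    sim: SimConfig = None
    filter_low: float = 1.0
    filter_high: float = 50.0
    reject_uv: float = 100.0
    evoked_mode: str = "per_presentation_index"
    pca_target: float = 0.60
    loading_threshold: float = 0.40
    svm_c: float = 1.0
    alpha_levels: tuple = (0.05, 0.01)
    save_epoch_files: bool = False
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed, **self.sim_overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_kwargs = raw.pop("sim", {})
        cfg = cls(**raw)
        if sim_kwargs:
            cfg.sim = SimConfig(seed=sim_kwargs.pop("seed", cfg.seed), **sim_kwargs)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = {
            k: (v.tolist() if isinstance(v, np.ndarray)
                else {kk: np.asarray(vv).tolist() for kk, vv in v.items()} if isinstance(v, dict)
                else v)
            for k, v in dataclasses.asdict(self.sim).items()
        }
        d["stages"] = list(self.stages)
        d["alpha_levels"] = list(self.alpha_levels)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, cohort=None, metas=None) -> dict:
    """Execute the enabled stages and write all artifacts to ``out_dir``.

    Pre-simulated input may be passed via ``cohort``/``metas`` (the simulate
    stage is then skipped).  Returns a dict of in-memory stage results plus
    the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    chash = config.config_hash()
    manifest: dict = {
        "config_hash": chash,
        "seed": config.seed,
        "eegrs_version": __version__,
        "numpy_version": np.__version__,
        "stages": sorted(stages),
        "counts": {},
    }
    results: dict = {"manifest": manifest}

    if cohort is None:
        if "simulate" not in stages:
            raise ValueError("no input cohort and simulate stage disabled")
        cohort, metas = generate_cohort(config.sim)
    manifest["counts"]["participants"] = len(cohort)
    save_meta(metas, out / "meta.csv")
    if config.save_epoch_files:
        for et in cohort:
            save_epochs(et, out / f"{et.participant_id}.h5")

    if "preprocess" in stages:
        cohort, logs = preprocess_cohort(cohort, config.filter_low, config.filter_high,
                                         config.reject_uv)
        from .containers import RejectionLog
        RejectionLog.to_frame(logs).to_csv(out / "rejection_log.csv", index=False)
        manifest["counts"]["epochs_kept"] = int(sum(log.kept_count for log in logs))
        manifest["counts"]["epochs_total"] = int(sum(log.total_count for log in logs))

    if not ({"energy", "rois", "lmm", "decode"} & stages):
        _write_manifest(manifest, out, chash)
        return results

    chan_energy = energy_table(cohort, metas, rois=None, mode=config.evoked_mode)
    manifest["counts"]["channel_energy_rows"] = len(chan_energy)

    rois = None
    if "rois" in stages:
        rois, models = derive_rois(chan_energy, cumulative_target=config.pca_target,
                                   loading_threshold=config.loading_threshold)
        rois.to_json(out / "rois.json")
        loadings = []
        for g, model in models.items():
            frame = pd.DataFrame(model.loadings, index=model.channels,
                                 columns=[f"F{j + 1}" for j in range(model.n_retained)])
            frame.insert(0, "group", g)
            loadings.append(frame)
        pd.concat(loadings).to_csv(out / "factor_loadings.csv")
        manifest["counts"]["rois"] = len(rois)
        results["rois"] = rois

    if "energy" in stages or rois is not None:
        roi_energy = energy_table(cohort, metas, rois=rois, mode=config.evoked_mode) \
            if rois is not None else chan_energy
        roi_energy.insert(0, "config_hash", chash)
        roi_energy.to_csv(out / "energy.csv", index=False)
        roi_energy = roi_energy.drop(columns="config_hash")
        manifest["counts"]["energy_rows"] = len(roi_energy)
        results["energy"] = roi_energy
    else:
        roi_energy = chan_energy

    if "lmm" in stages:
        ladder = run_ladder(roi_energy, metas)
        report = ladder.to_dict()
        report["config_hash"] = chash
        (out / "lmm_report.json").write_text(json.dumps(report, indent=2, default=float))
        results["ladder"] = ladder

    decoding_df = None
    if "decode" in stages:
        fm = build_rs_features(roi_energy, metas,
                               roi_order=rois.names if rois is not None else None)
        fm.X.to_csv(out / "features.csv")
        plan = make_fold_plan(meta_frame(metas))
        decoding_df = run_decoding(fm, plan, C=config.svm_c)
        manifest["counts"]["features"] = fm.n_features
        manifest["counts"]["trials"] = len(fm.X)
        manifest["counts"]["bootstrap_subsets"] = plan.n_subsets
        results["decoding"] = decoding_df

    if "signif" in stages and decoding_df is not None:
        n_eval = len(plan.subsets[0]) * 2 * config.sim.n_stimuli
        spec05 = SignificanceSpec(n=n_eval, alpha=config.alpha_levels[0], m=len(decoding_df))
        spec01 = SignificanceSpec(n=n_eval, alpha=config.alpha_levels[1], m=len(decoding_df))
        flagged, sig_meta = flag_significant(decoding_df, spec05, spec01)
        sig_meta["config_hash"] = chash
        flagged.insert(0, "config_hash", chash)
        flagged.to_csv(out / "decoding.csv", index=False)
        (out / "significance.json").write_text(json.dumps(sig_meta, indent=2))
        manifest["counts"]["significant_features"] = int((flagged["significance"] != "ns").sum())
        results["decoding"] = flagged
    elif decoding_df is not None:
        decoding_df.insert(0, "config_hash", chash)
        decoding_df.to_csv(out / "decoding.csv", index=False)

    _write_manifest(manifest, out, chash)
    return results


def _write_manifest(manifest: dict, out: Path, chash: str) -> None:
    manifest["artifact_hashes"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".json") and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
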