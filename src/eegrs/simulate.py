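"""Synthetic EEG cohort generator.

Emulates the structure of the auditory habituation study the pipeline
analyzes: each participant hears 18 pseudowords, each repeated 10 times, and
the epoched response (800 ms at 250 Hz, 99 channels) is modeled as

* a phase-locked evoked waveform, identical across presentations (a damped
  sine template with a smooth anterior-posterior scalp gradient),
* non-phase-locked induced oscillations from a small set of orthogonal
  spatial sources, amplitude-modulated by a subgroup-specific per-presentation
  gain profile (the planted repetition-suppression effect), with a fresh
  uniform random phase per epoch so the component cancels in across-trial
  averages,
* white sensor noise, and
* occasional high-amplitude artifacts exceeding the rejection threshold.

Habituation profiles follow the pattern the study reports: controls suppress
after the first presentation, high-NVIQ FXS participants after the third, and
low-NVIQ FXS participants not at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochTensor, ParticipantMeta, subgroup_for
from .montage import REGION_SEEDS, default_montage, region_topographies

__all__ = ["SimConfig", "generate_cohort", "rs_profile", "default_rs_profiles"]


class ConfigurationError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


def default_rs_profiles(n_presentations: int = 10, h: float = 1.3) -> dict[str, np.ndarray]:
    """Per-presentation induced-amplitude gain vectors a_g(p) per subgroup.

    ``h > 1`` is the pre-suppression gain: controls drop to baseline after
    presentation 1, the high-NVIQ FXS profile after presentation 3, and the
    low-NVIQ FXS profile stays elevated (no suppression).
    """
    control = np.ones(n_presentations)
    control[0] = h
    fxs_high = np.ones(n_presentations)
    fxs_high[: min(3, n_presentations)] = h
    fxs_low = np.full(n_presentations, h)
    return {"control": control, "fxs_high": fxs_high, "fxs_low": fxs_low}


# study demographics used as sampling defaults: NVIQ ranges per subgroup,
# age range shared by all groups, and the observed female fraction per group
DEFAULT_NVIQ_RANGES = {"control": (87, 129), "fxs_low": (32, 42), "fxs_high": (52, 93)}
DEFAULT_FEMALE_FRACTION = {"control": 11 / 26, "fxs_low": 0.0, "fxs_high": 4 / 6}


@dataclass
class SimConfig:
    """Full parameterization of one synthetic cohort.

    Defaults mirror the study conditions: 26 controls, 8 low-NVIQ and 6
    high-NVIQ FXS participants; 18 pseudowords x 10 presentations; 99
    channels, 200 samples (800 ms at 250 Hz).  ``topographies`` (unit-norm,
    mutually orthogonal rows) and ``source_weights`` (per-subgroup source
    activation) default to seven contiguous scalp-region indicators with the
    FXS subgroups driving the first two (central, frontal-left) and controls
    the remaining five, reproducing the two-factor / five-factor group
    structure the spatial PCA stage is meant to recover.
    """

    n_controls: int = 26
    n_fxs_low: int = 8
    n_fxs_high: int = 6
    n_stimuli: int = 18
    n_presentations: int = 10
    n_channels: int = 99
    n_samples: int = 200
    sample_rate: float = 250.0
    rs_profiles: dict = None
    evoked_amplitude: float = 6.0
    induced_amplitude: float = 10.0
    induced_freq: float = 10.0
    induced_amp_cv: object = None  # float, or subgroup -> float; see __post_init__
    source_subject_cv: float = 0.4
    noise_sd: float = 10.0
    topographies: np.ndarray = None
    source_names: list = None
    source_weights: dict = None
    source_rs_profiles: dict = None  # optional subgroup -> (n_sources, n_presentations)
    source_clusters: dict = None     # subgroup -> per-source amplitude-coherence cluster id
    artifact_rate: float = 0.02
    artifact_amplitude: float = 150.0
    nviq_ranges: dict = field(default_factory=lambda: dict(DEFAULT_NVIQ_RANGES))
    age_range: tuple = (9.0, 32.0)
    female_fraction: dict = field(default_factory=lambda: dict(DEFAULT_FEMALE_FRACTION))
    seed: int = 0
    store_components: bool = False

    def __post_init__(self):
        for name in ("n_controls", "n_fxs_low", "n_fxs_high", "n_stimuli",
                     "n_presentations", "n_channels", "n_samples"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.rs_profiles is None:
            self.rs_profiles = default_rs_profiles(self.n_presentations)
        self.rs_profiles = {g: np.asarray(v, dtype=float) for g, v in self.rs_profiles.items()}
        for g, v in self.rs_profiles.items():
            if v.shape != (self.n_presentations,):
                raise ConfigurationError(f"gain vector for {g!r} has wrong length")
            if np.any(v < 0):
                raise ConfigurationError(f"gain vector for {g!r} has negative entries")
        if self.topographies is None:
            montage = default_montage(self.n_channels)
            topo, names = region_topographies(montage)
            self.topographies = topo
            if self.source_names is None:
                self.source_names = names
        else:
            self.topographies = np.atleast_2d(np.asarray(self.topographies, dtype=float))
            if self.topographies.shape[1] != self.n_channels:
                raise ConfigurationError("topography length does not match n_channels")
            if self.source_names is None:
                self.source_names = [f"S{j + 1}" for j in range(len(self.topographies))]
        norms = np.linalg.norm(self.topographies, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ConfigurationError("topographies must have unit Euclidean norm")
        gram = self.topographies @ self.topographies.T
        off = gram - np.diag(np.diag(gram))
        if np.max(np.abs(off)) > 1e-8:
            raise ConfigurationError("topographies must be mutually orthogonal")
        n_sources = len(self.topographies)
        if self.source_weights is None:
            # controls drive five focal sources (temporal-left through
            # occipital in the default region order) independently; FXS
            # participants drive all regions, but coherently within two
            # large-scale clusters (see source_clusters), reflecting the
            # increased spatial spreading of synchronized activity reported
            # for this population
            w_fxs = np.ones(n_sources)
            w_ctl = np.zeros(n_sources)
            if n_sources == 7:
                # control source amplitudes placed in the regime where five
                # focal sources plus sensor noise carry ~60% cumulative
                # variance in exactly five factors (order: central,
                # frontal-left, temporal-left, fronto-central, frontal-right,
                # temporal-right, occipital); FXS sources run at full
                # amplitude, consistent with the hyperexcitability of the
                # population
                w_ctl[2:] = [0.39, 0.50, 0.50, 0.39, 0.31]
            else:
                w_ctl[min(2, n_sources):] = 1.0
            if not w_ctl.any():  # fewer than 3 sources: controls share them
                w_ctl[:] = 1.0
            self.source_weights = {"control": w_ctl, "fxs_low": w_fxs.copy(), "fxs_high": w_fxs.copy()}
        self.source_weights = {g: np.asarray(v, dtype=float) for g, v in self.source_weights.items()}
        for g, v in self.source_weights.items():
            if v.shape != (n_sources,):
                raise ConfigurationError(f"source weights for {g!r} have wrong length")
        if self.source_clusters is None:
            # default region order: central, frontal-left, temporal-left,
            # fronto-central, frontal-right, temporal-right, occipital
            if n_sources == 7:
                fxs_clusters = (0, 0, 1, 0, 0, 1, 1)  # anterior-central vs posterior-lateral
            else:
                fxs_clusters = tuple(range(n_sources))
            self.source_clusters = {
                "control": tuple(range(n_sources)),
                "fxs_low": fxs_clusters,
                "fxs_high": fxs_clusters,
            }
        if self.source_rs_profiles is None and n_sources == 7:
            # repetition gains are regional: controls habituate over the
            # anterior/temporal sources (auditory RS is fronto-central and
            # temporal, not occipital); the FXS profiles ride on the
            # anterior-central cluster where the group's repetition effects
            # concentrate
            ctl_regions, fxs_regions = (2, 3, 4, 5), (0, 1, 3, 4)
            self.source_rs_profiles = {}
            for g, active in (("control", ctl_regions),
                              ("fxs_low", fxs_regions), ("fxs_high", fxs_regions)):
                mat = np.ones((n_sources, self.n_presentations))
                for j in active:
                    mat[j] = self.rs_profiles[g]
                self.source_rs_profiles[g] = mat
        self.source_clusters = {g: tuple(int(c) for c in v) for g, v in self.source_clusters.items()}
        for g, v in self.source_clusters.items():
            if len(v) != n_sources:
                raise ConfigurationError(f"source clusters for {g!r} have wrong length")
        # trial-to-trial induced-power variability; FXS shows elevated neural
        # response variability, so the default is subgroup-dependent
        if self.induced_amp_cv is None:
            self.induced_amp_cv = {"control": 0.75, "fxs_low": 1.2, "fxs_high": 1.2}
        if not isinstance(self.induced_amp_cv, dict):
            cv = float(self.induced_amp_cv)
            self.induced_amp_cv = {g: cv for g in ("control", "fxs_low", "fxs_high")}
        if self.source_rs_profiles is not None:
            self.source_rs_profiles = {
                g: np.asarray(v, dtype=float) for g, v in self.source_rs_profiles.items()
            }
            for g, v in self.source_rs_profiles.items():
                if v.shape != (n_sources, self.n_presentations):
                    raise ConfigurationError(
                        f"per-source gain matrix for {g!r} must be (n_sources, n_presentations)"
                    )
                if np.any(v < 0):
                    raise ConfigurationError(f"per-source gains for {g!r} have negative entries")
        if self.noise_sd == 0 and self.evoked_amplitude == 0 and self.induced_amplitude == 0:
            raise DegenerateDataError("all signal amplitudes and noise are zero")
        if not 0 <= self.artifact_rate < 1:
            raise ConfigurationError("artifact_rate must be in [0, 1)")

    @property
    def n_participants(self) -> int:
        return self.n_controls + self.n_fxs_low + self.n_fxs_high


def rs_profile(group: str, p: int, config: SimConfig) -> float:
    """Gain a_g(p) for 1-based presentation index ``p`` of subgroup ``group``."""
    if group not in config.rs_profiles:
        raise KeyError(f"unknown group label {group!r}")
    if not 1 <= p <= config.n_presentations:
        raise ValueError(f"presentation index {p} out of range")
    return float(config.rs_profiles[group][p - 1])


def _evoked_template(config: SimConfig) -> np.ndarray:
    """Damped-sine evoked waveform, peak amplitude = evoked_amplitude (uV)."""
    t = np.arange(config.n_samples) / config.sample_rate
    wave = np.exp(-t / 0.25) * np.sin(2 * np.pi * 5.0 * t)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave / peak * config.evoked_amplitude
    return wave


def _evoked_pattern(config: SimConfig) -> np.ndarray:
    """Smooth anterior-posterior spatial gradient, peak channel = 1."""
    montage = default_montage(config.n_channels)
    pat = 0.6 + 0.4 * montage["y"].to_numpy()
    return pat / np.max(np.abs(pat))


def _simulate_participant(
    pid: str,
    subgroup: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> EpochTensor:
    S, P, C, T = config.n_stimuli, config.n_presentations, config.n_channels, config.n_samples
    t = np.arange(T) / config.sample_rate
    weights = config.source_weights[subgroup]     # (J,)
    topo = config.topographies                    # (J, C)
    # topographies are stored unit-norm; scale each so its peak channel
    # carries the nominal source amplitude in microvolts
    peak = np.max(np.abs(topo), axis=1)
    proj = topo / peak[:, None]                   # (J, C)
    J = len(topo)

    evoked = _evoked_pattern(config)[:, None] * _evoked_template(config)[None, :]  # (C, T)

    # amplitude fluctuations and phase are coherent within a subgroup-specific
    # source cluster: draw per cluster, then expand to sources
    clusters = np.asarray(config.source_clusters[subgroup])
    _, cluster_idx = np.unique(clusters, return_inverse=True)
    n_clusters = cluster_idx.max() + 1
    # per-(participant, cluster) strength: lognormal, mean 1, cv source_subject_cv
    subj_amp = _lognormal(rng, config.source_subject_cv, size=n_clusters)[cluster_idx]
    # per-epoch amplitude variability is shared within a cluster (a coherent
    # power envelope); phases stay independent per source so that sources do
    # not interfere coherently at the sensors
    amp_cv = config.induced_amp_cv[subgroup]
    epoch_amp = _lognormal(rng, amp_cv, size=(S, P, n_clusters))[:, :, cluster_idx]
    phase = rng.uniform(0, 2 * np.pi, size=(S, P, J))

    # per-presentation gains: shared subgroup profile, or per-source profiles
    if config.source_rs_profiles is not None and subgroup in config.source_rs_profiles:
        gains = config.source_rs_profiles[subgroup].T  # (P, J)
    else:
        gains = np.repeat(config.rs_profiles[subgroup][:, None], J, axis=1)  # (P, J)
    amp = (config.induced_amplitude * weights * subj_amp)[None, None, :] * epoch_amp  # (S,P,J)
    amp = amp * gains[None, :, :]
    osc = np.sin(2 * np.pi * config.induced_freq * t[None, None, None, :] + phase[..., None])  # (S,P,J,T)
    induced = np.einsum("spjt,jc->spct", amp[..., None] * osc, proj)

    noise = rng.normal(0.0, config.noise_sd, size=(S, P, C, T)) if config.noise_sd > 0 else 0.0

    data = evoked[None, None, :, :] + induced + noise

    if config.artifact_rate > 0:
        hit = rng.random(size=(S, P)) < config.artifact_rate
        width = min(25, T)
        for s, p in zip(*np.nonzero(hit)):
            ch = rng.integers(0, C)
            start = rng.integers(0, T - width + 1)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[s, p, ch, start:start + width] += sign * config.artifact_amplitude

    components = None
    if config.store_components:
        components = {
            "evoked": np.broadcast_to(evoked, (S, P, C, T)).copy(),
            "induced": induced,
        }
    return EpochTensor(
        participant_id=pid,
        data=data,
        channel_names=[f"E{i + 1}" for i in range(C)],
        sample_rate=config.sample_rate,
        components=components,
    )


def _lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal multipliers with mean 1 and coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _sample_meta(pid: str, subgroup: str, config: SimConfig, rng: np.random.Generator) -> ParticipantMeta:
    lo, hi = config.nviq_ranges[subgroup]
    nviq = int(rng.integers(lo, hi + 1))
    age = float(np.round(rng.uniform(*config.age_range), 1))
    sex = "F" if rng.random() < config.female_fraction.get(subgroup, 0.5) else "M"
    group = "control" if subgroup == "control" else "fxs"
    return ParticipantMeta(participant_id=pid, group=group, nviq=nviq, age=age, sex=sex)


def generate_cohort(config: SimConfig) -> tuple[list[EpochTensor], list[ParticipantMeta]]:
    """Generate one cohort: a list of epoch tensors and matching metadata.

    Deterministic: the master seed spawns one independent substream per
    participant, so identical ``(config, seed)`` yields bit-identical output
    and regenerating a subset of participants reproduces their data.
    """
    labels = (
        [("control", i) for i in range(config.n_controls)]
        + [("fxs_low", i) for i in range(config.n_fxs_low)]
        + [("fxs_high", i) for i in range(config.n_fxs_high)]
    )
    seqs = np.random.SeedSequence(config.seed).spawn(len(labels))
    epochs, metas = [], []
    for (subgroup, i), seq in zip(labels, seqs):
        prefix = {"control": "ctl", "fxs_low": "fxl", "fxs_high": "fxh"}[subgroup]
        pid = f"{prefix}{i + 1:02d}"
        rng = np.random.default_rng(seq)
        meta = _sample_meta(pid, subgroup, config, rng)
        epochs.append(_simulate_participant(pid, subgroup, config, rng))
        metas.append(meta)
    return epochs, metas


def fxs_region_names() -> list[str]:
    """Region order used by the default source layout (first two: FXS sources)."""
    return list(REGION_SEEDS)
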