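"""Synthetic EEG cohorts with a planted brain-behavior correlation.

The generator emulates the structure of the study cohort this pipeline
analyzes: three diagnostic groups (ASD, ADHD, CONTROL) of 21 adults each, a
14-channel montage sampled at 128 Hz, about 60,000 samples per reasoning
condition, and one behavioral row (age, SAM emotional-state ratings,
confidence) per subject and condition.

Each channel signal is a mixture of three unit-variance components — white
noise, pink (1/f) noise, and a fixed-frequency alpha-band sinusoid with
random phase — whose non-negative mixing weights sum to one. A higher white
weight raises small-scale sample entropy; pink-dominated signals have
flatter entropy-vs-scale curves; the sinusoid is nearly perfectly regular.
Group/channel contrasts in the default mixing profile give the right
frontal-central and anterio-frontal channels elevated complexity in the ASD
group, with analogous single-channel bumps in the other groups.

Behavior is planted on top of the realized signal complexity: each subject's
scale-averaged entropy features are projected onto a loading vector, the
projection is standardized across the cohort, and affine maps (plus Gaussian
noise) place it on the SAM 1-9 integer scale and the 0-100 confidence scale.
A one-hot loading with zero noise therefore makes behavior a deterministic
monotone function of one channel's complexity — the signal the PLSC stage
must recover — while a zero loading yields behavior independent of the brain
features (the null case for permutation calibration).

Reproducibility: every subject/condition owns an independent RNG stream
derived from (master seed, group index, subject index, condition), so
resizing one group never reshuffles other subjects' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from scipy import stats

from .entropy import MSEParams, mse_curve
from .errors import ValidationError
from .io import (
    CONDITIONS,
    DEFAULT_CHANNELS,
    DEFAULT_MONTAGE,
    GROUPS,
    ChannelMontage,
    EEGRecording,
    SubjectBehavior,
    write_behavior,
    write_eeg_csv,
    write_eeg_edf,
)

#: Demographic defaults per group: (mean age, SD) in years.
DEFAULT_AGE_PARAMS = ((31.2, 10.52), (28.65, 8.75), (28.05, 6.152))

SIGNAL_SCALE_UV = 20.0  # overall amplitude of the unit-variance mixture
MIN_ADULT_AGE = 18.0


def default_complexity_profile(n_channels: int = 14) -> np.ndarray:
    """(group, channel, component) mixing weights: white / pink / oscillation.

    Baseline is pink-dominated; two channels per group get a white-noise bump
    so each group has its own high-complexity signature (right frontal-central
    and anterio-frontal for ASD, right frontal and left occipital for ADHD,
    left frontal and left occipital for CONTROL).
    """
    profile = np.tile([0.35, 0.55, 0.10], (len(GROUPS), n_channels, 1))
    if n_channels == len(DEFAULT_CHANNELS):
        idx = {c: i for i, c in enumerate(DEFAULT_CHANNELS)}
        bumps = {
            "ASD": (("FC6", (0.65, 0.30, 0.05)), ("AF4", (0.60, 0.35, 0.05))),
            "ADHD": (("F4", (0.60, 0.35, 0.05)), ("O1", (0.55, 0.40, 0.05))),
            "CONTROL": (("F3", (0.55, 0.40, 0.05)), ("O1", (0.50, 0.45, 0.05))),
        }
        for g, chans in bumps.items():
            for ch, w in chans:
                profile[GROUPS.index(g), idx[ch]] = w
    return profile


def default_behavior_loading(n_channels: int = 14) -> np.ndarray:
    """Loading linking channel complexity to behavior; heaviest on FC6/AF4."""
    loading = np.full(n_channels, 0.1)
    if n_channels == len(DEFAULT_CHANNELS):
        idx = {c: i for i, c in enumerate(DEFAULT_CHANNELS)}
        for ch, w in (("FC6", 0.60), ("AF4", 0.45), ("F4", 0.30), ("O1", 0.25)):
            loading[idx[ch]] = w
    return loading


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines a synthetic dataset, given a seed."""

    group_sizes: tuple[int, int, int] = (21, 21, 21)
    n_channels: int = 14
    sampling_rate: float = 128.0
    n_samples: int = 60_000
    complexity_profile: np.ndarray = field(
        default_factory=default_complexity_profile
    )
    behavior_loading: np.ndarray = field(default_factory=default_behavior_loading)
    behavior_noise_sd: float = 0.5
    age_params: tuple[tuple[float, float], ...] = DEFAULT_AGE_PARAMS
    oscillation_freq_hz: float = 8.0
    mse_params: MSEParams = field(default_factory=MSEParams)
    rng_seed: int = 0

    def __post_init__(self):
        if len(self.group_sizes) != len(GROUPS):
            raise ValidationError(f"need {len(GROUPS)} group sizes")
        if any(g < 2 for g in self.group_sizes):
            raise ValidationError("every group needs at least 2 subjects")
        if self.n_samples < 100 * self.mse_params.tau_max:
            raise ValidationError(
                f"n_samples={self.n_samples} < 100 * tau_max="
                f"{100 * self.mse_params.tau_max}: not enough points per scale"
            )
        profile = np.asarray(self.complexity_profile, float)
        if profile.shape != (len(GROUPS), self.n_channels, 3):
            raise ValidationError(
                f"complexity_profile must have shape "
                f"({len(GROUPS)}, {self.n_channels}, 3), got {profile.shape}"
            )
        _validate_weights(profile.reshape(-1, 3))
        object.__setattr__(self, "complexity_profile", profile)
        loading = np.asarray(self.behavior_loading, float)
        if loading.shape != (self.n_channels,):
            raise ValidationError(
                f"behavior_loading must have length {self.n_channels}"
            )
        object.__setattr__(self, "behavior_loading", loading)
        if self.behavior_noise_sd < 0:
            raise ValidationError("behavior_noise_sd must be >= 0")
        if len(self.age_params) != len(GROUPS):
            raise ValidationError(f"need age params for {len(GROUPS)} groups")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes))

    def to_dict(self) -> dict:
        return {
            "group_sizes": list(self.group_sizes),
            "n_channels": self.n_channels,
            "sampling_rate": self.sampling_rate,
            "n_samples": self.n_samples,
            "complexity_profile": np.asarray(self.complexity_profile).tolist(),
            "behavior_loading": np.asarray(self.behavior_loading).tolist(),
            "behavior_noise_sd": self.behavior_noise_sd,
            "age_params": [list(p) for p in self.age_params],
            "oscillation_freq_hz": self.oscillation_freq_hz,
            "mse_params": {
                "m": self.mse_params.m, "r_factor": self.mse_params.r_factor,
                "tau_max": self.mse_params.tau_max, "r_mode": self.mse_params.r_mode,
            },
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "mse_params" in d:
            d["mse_params"] = MSEParams(**d["mse_params"])
        if "group_sizes" in d:
            d["group_sizes"] = tuple(d["group_sizes"])
        if "age_params" in d:
            d["age_params"] = tuple(tuple(p) for p in d["age_params"])
        for k in ("complexity_profile", "behavior_loading"):
            if k in d:
                d[k] = np.asarray(d[k], float)
        return cls(**d)


def _validate_weights(weights: np.ndarray):
    w = np.asarray(weights, float)
    if (w < 0).any():
        raise ValidationError("mixing weights must be non-negative")
    sums = w.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValidationError("mixing weights must sum to 1 per (group, channel)")


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, normalized to unit variance."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spectrum * shaping, n)
    return x / x.std()


def simulate_signal(
    n_samples: int,
    weights: np.ndarray,
    rng: np.random.Generator,
    sampling_rate: float = 128.0,
    oscillation_freq_hz: float = 8.0,
) -> np.ndarray:
    """One channel signal: weighted mix of white, pink and sinusoid components.

    Components have unit variance, so the weights set their amplitude ratios;
    the mixture is scaled to a plausible microvolt range.
    """
    if n_samples <= 0:
        raise ValidationError(f"n_samples must be positive, got {n_samples}")
    _validate_weights(np.asarray(weights, float)[None, :])
    w_white, w_pink, w_osc = np.asarray(weights, float)
    parts = np.zeros(n_samples)
    # draw every stream unconditionally so the RNG state does not depend on
    # which weights happen to be zero
    white = rng.standard_normal(n_samples)
    pink = pink_noise(n_samples, rng)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n_samples) / sampling_rate
    osc = np.sqrt(2.0) * np.sin(2 * np.pi * oscillation_freq_hz * t + phase)
    parts = w_white * white + w_pink * pink + w_osc * osc
    return SIGNAL_SCALE_UV * parts


def simulate_behavior(
    subject_id: str,
    group: str,
    condition: str,
    features: np.ndarray,
    loading: np.ndarray,
    noise_sd: float,
    age_params: tuple[float, float],
    rng: np.random.Generator,
    score_loc: float = 0.0,
    score_scale: float = 1.0,
) -> SubjectBehavior:
    """One behavioral row generated from a subject's complexity features.

    The latent score (features . loading), standardized by
    (score_loc, score_scale), is mapped affinely onto the SAM 1-9 scale
    (rounded to integers) and the 0-100 confidence scale, with independent
    Gaussian noise of ``noise_sd`` added per measure. Age is drawn from the
    group's normal distribution truncated below at 18 years.
    """
    features = np.asarray(features, float)
    loading = np.asarray(loading, float)
    if features.shape != loading.shape:
        raise ValidationError(
            f"loading length {loading.shape} != feature length {features.shape}"
        )
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    z = (float(features @ loading) - score_loc) / score_scale

    def noisy() -> float:
        return z + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)

    sam = tuple(
        int(np.clip(np.round(5.0 + 2.5 * noisy()), 1, 9)) for _ in range(3)
    )
    confidence = float(np.clip(50.0 + 15.0 * noisy(), 0.0, 100.0))
    mu, sd = age_params
    a = (MIN_ADULT_AGE - mu) / sd
    age = float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))
    return SubjectBehavior(
        subject_id=subject_id, group=group, condition=condition, age=age,
        sam_valence=sam[0], sam_arousal=sam[1], sam_dominance=sam[2],
        confidence_percent=confidence,
    )


@dataclass
class SyntheticDataset:
    """Recordings + behavior rows + the realized complexity features."""

    recordings: list[EEGRecording]
    behavior: list[SubjectBehavior]
    features: dict[str, "np.ndarray | object"]  # condition -> DataFrame
    config: SimulationConfig

    def validate(self):
        keys_r = {(r.subject_id, r.condition) for r in self.recordings}
        keys_b = {(b.subject_id, b.condition) for b in self.behavior}
        if len(keys_r) != len(self.recordings) or len(keys_b) != len(self.behavior):
            raise ValidationError("duplicate (subject, condition) entries")
        if keys_r != keys_b:
            raise ValidationError("recordings and behavior rows are misaligned")
        group_r = {r.subject_id: r.group for r in self.recordings}
        for b in self.behavior:
            if group_r[b.subject_id] != b.group:
                raise ValidationError(
                    f"group mismatch for subject {b.subject_id}"
                )

    def to_dir(
        self, out_dir: str | Path, eeg_format: Literal["csv", "edf"] = "csv"
    ) -> Path:
        """Write EEG files, behavior.csv and config.yaml into a directory."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        writer = write_eeg_csv if eeg_format == "csv" else write_eeg_edf
        for rec in self.recordings:
            name = f"{rec.subject_id}_{rec.group}_{rec.condition}.{eeg_format}"
            writer(rec, out_dir / name)
        write_behavior(self.behavior, out_dir / "behavior.csv")
        (out_dir / "config.yaml").write_text(
            yaml.safe_dump(self.config.to_dict(), sort_keys=True)
        )
        return out_dir


def _subject_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_cohort(config: SimulationConfig = SimulationConfig()) -> SyntheticDataset:
    """Generate a full dataset: signals, realized entropy features, behavior.

    The behavioral planting uses the features actually computed from the
    generated signals (scale-averaged sample entropy with
    ``config.mse_params``), standardized across the cohort per condition.
    """
    import pandas as pd  # local import to keep module load light

    montage = (
        DEFAULT_MONTAGE if config.n_channels == len(DEFAULT_CHANNELS)
        else ChannelMontage(tuple(f"CH{i+1}" for i in range(config.n_channels)),
                            locations={})
    )
    recordings: list[EEGRecording] = []
    feature_rows: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    subject_meta: list[tuple[str, str, int, int]] = []  # id, group, g_idx, i

    for g_idx, group in enumerate(GROUPS):
        for i in range(config.group_sizes[g_idx]):
            sid = f"{group}{i + 1:02d}"
            subject_meta.append((sid, group, g_idx, i))
            for c_idx, condition in enumerate(CONDITIONS):
                rng = _subject_rng(config.rng_seed, g_idx, i, c_idx)
                sig = np.vstack([
                    simulate_signal(
                        config.n_samples,
                        config.complexity_profile[g_idx, ch],
                        rng,
                        config.sampling_rate,
                        config.oscillation_freq_hz,
                    )
                    for ch in range(config.n_channels)
                ])
                recordings.append(EEGRecording(
                    sid, group, condition, config.sampling_rate, sig, montage
                ))
                feats = np.array([
                    mse_curve(sig[ch], config.mse_params).mean()
                    for ch in range(config.n_channels)
                ])
                feature_rows[condition].append(feats)

    subject_ids = [m[0] for m in subject_meta]
    features = {
        c: pd.DataFrame(
            np.vstack(rows), index=pd.Index(subject_ids, name="subject_id"),
            columns=list(montage.channels),
        )
        for c, rows in feature_rows.items()
    }

    behavior: list[SubjectBehavior] = []
    for c_idx, condition in enumerate(CONDITIONS):
        raw = features[condition].to_numpy() @ config.behavior_loading
        loc = float(raw.mean())
        scale = float(raw.std())
        if scale == 0:
            scale = 1.0
        for sid, group, g_idx, i in subject_meta:
            rng = _subject_rng(config.rng_seed, g_idx, i, c_idx, 1)
            behavior.append(simulate_behavior(
                sid, group, condition,
                features[condition].loc[sid].to_numpy(),
                config.behavior_loading, config.behavior_noise_sd,
                config.age_params[g_idx], rng,
                score_loc=loc, score_scale=scale,
            ))

    dataset = SyntheticDataset(recordings, behavior, features, config)
    dataset.validate()
    return dataset
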