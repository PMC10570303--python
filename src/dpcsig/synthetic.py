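"""Synthetic trial-structured fMRI datasets with a planted social-support signature.

The generator emulates a two-condition emotion-regulation experiment: on each
trial a participant recalls a negative autobiographical memory and either
imagines a supportive conversation with a peer (``imagined_support``) or dwells
on their own feelings (``self_feel``).  Each trial is a cleaned parcel x time
matrix (z-score units).  A rank-1 spatio-temporal pattern ``w g(t)``' is planted
with opposite sign in the two conditions, on top of a participant-specific
spatial baseline, a condition-independent evoked response shared by all trials,
and AR(1)-in-time / white-in-space noise.

Five-point negativity ratings are coupled to each trial's *true signature
expression* and three trait variables (loneliness, life satisfaction, support
nominations) are coupled to each participant's mean expression over
imagined-support trials, so every downstream stage of the pipeline can be
checked against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CONDITION_SUPPORT",
    "CONDITION_SELF",
    "CONDITIONS",
    "CONDITION_SIGNS",
    "SimConfig",
    "SimConfigError",
    "TrialRecord",
    "GroundTruth",
    "Dataset",
    "VoxelSession",
    "default_temporal_profile",
    "generate_dataset",
    "generate_voxel_session",
]

CONDITION_SUPPORT = "imagined_support"
CONDITION_SELF = "self_feel"
CONDITIONS = (CONDITION_SUPPORT, CONDITION_SELF)
#: sign of the planted pattern per condition (support expresses the signature
#: positively; self-feel negatively, so the condition means straddle zero).
CONDITION_SIGNS = {CONDITION_SUPPORT: 1.0, CONDITION_SELF: -1.0}

TARGET_SUPPORT_PROVIDER = "support_provider"
TARGET_NON_PROVIDER = "non_support_provider"
TARGET_SELF = "self"

#: instrument scales: (population base level, residual noise SD).
#: loneliness = ULS-8 item mean (1-4); life_satisfaction = SWLS sum (5-35);
#: support_count = peer nominations, integer 0-6 (cohort mean 3.86, SD 1.81).
TRAIT_SCALES: Dict[str, Tuple[float, float]] = {
    "loneliness": (2.2, 0.45),
    "life_satisfaction": (23.0, 6.0),
    "support_count": (3.86, 1.7),
}


class SimConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


def _default_trait_slopes() -> Dict[str, float]:
    # Slopes of trait vs. participant mean signature expression, mirroring the
    # sign/magnitude pattern of the cohort effects (lonelier people express the
    # signature less; more satisfied / better supported people express it more).
    return {"loneliness": -0.22, "life_satisfaction": 0.27, "support_count": 0.58}


@dataclass(frozen=True)
class SimConfig:
    """Study-design and effect-size parameters of the simulated cohort.

    Defaults mirror the emulated study: 95 participants in two recruitment
    waves (48/47), 12 trials each, 214 parcels x 20 timepoints at TR = 1 s,
    56% imagined-support trials, and a sparse planted spatial pattern over
    20 parcels.
    """

    n_participants: int = 95
    trials_per_participant: int = 12
    p_support: float = 0.56
    n_parcels: int = 214
    n_timepoints: int = 20
    tr_seconds: float = 1.0
    #: planted condition-signal SD over matrix entries, per unit noise SD.
    snr: float = 1.0
    ar_coef: float = 0.3
    n_signal_parcels: int = 20
    #: drop in expected negativity rating per unit of true signature expression.
    rating_slope: float = 0.5
    trait_slopes: Dict[str, float] = field(default_factory=_default_trait_slopes)
    seed: int = 0
    # heterogeneity / nuisance structure
    gain_sd_between: float = 0.3
    gain_sd_within: float = 0.25
    baseline_pattern_sd: float = 0.5
    common_response_amp: float = 0.5
    rating_noise_sd: float = 0.8
    rating_intercept_sd: float = 0.3
    trait_wave_effect: float = 0.2
    #: optional override of the planted temporal profile g(t) (len n_timepoints).
    temporal_profile: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_participants", "trials_per_participant", "n_parcels",
                     "n_signal_parcels"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise SimConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.n_timepoints < 2:
            raise SimConfigError(f"n_timepoints must be >= 2, got {self.n_timepoints!r}")
        if not (0.0 < self.p_support < 1.0):
            raise SimConfigError(f"p_support must be in (0, 1), got {self.p_support!r}")
        if self.snr < 0:
            raise SimConfigError(f"snr must be >= 0, got {self.snr!r}")
        if not (0.0 <= self.ar_coef < 1.0):
            raise SimConfigError(f"ar_coef must be in [0, 1), got {self.ar_coef!r}")
        if self.n_signal_parcels > self.n_parcels:
            raise SimConfigError(
                f"n_signal_parcels ({self.n_signal_parcels}) cannot exceed "
                f"n_parcels ({self.n_parcels})")
        if self.tr_seconds <= 0:
            raise SimConfigError(f"tr_seconds must be > 0, got {self.tr_seconds!r}")
        for name in ("gain_sd_between", "gain_sd_within", "baseline_pattern_sd",
                     "common_response_amp", "rating_noise_sd", "rating_intercept_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if self.temporal_profile is not None:
            profile = np.asarray(self.temporal_profile, dtype=float)
            if profile.shape != (self.n_timepoints,):
                raise SimConfigError(
                    f"temporal_profile must have length n_timepoints "
                    f"({self.n_timepoints}), got shape {profile.shape}")
            if not np.all(np.isfinite(profile)) or np.allclose(profile, profile[0]):
                raise SimConfigError("temporal_profile must be finite and non-constant")


@dataclass
class TrialRecord:
    """One trial: a cleaned parcel x time matrix plus its behavioral metadata."""

    participant_id: str
    memory_id: str
    condition: str
    target_type: str
    negativity_rating: int
    baseline_negativity: int
    data: np.ndarray  # (n_parcels, n_timepoints), z-score units


@dataclass
class GroundTruth:
    """Planted structure used by recovery tests; no counterpart in real data."""

    spatial_pattern: np.ndarray          # unit-norm w over parcels
    temporal_profile: np.ndarray         # g(t), RMS 1
    condition_signs: Dict[str, float]
    rating_slope: float
    trait_slopes: Dict[str, float]
    expression: np.ndarray               # per-trial true signature expression
    signal_parcels: np.ndarray           # indices of nonzero entries of w
    participant_mean_expression: pd.Series  # mean expression over support trials
    snr: float


class Dataset(NamedTuple):
    trials: List[TrialRecord]
    traits: pd.DataFrame
    truth: GroundTruth


class VoxelSession(NamedTuple):
    """One simulated run at voxel resolution plus its generating ground truth."""

    image: "object"        # nibabel Nifti1Image, 4D
    atlas: "object"        # nibabel Nifti1Image, integer labels, 0 = background
    confounds: pd.DataFrame
    events: pd.DataFrame
    planted_series: np.ndarray  # (n_volumes, n_parcels) planted parcel signal
    trials: List[TrialRecord]


def default_temporal_profile(n_timepoints: int, tr_seconds: float = 1.0) -> np.ndarray:
    """Smooth evoked-response-like bump (gamma kernel, peak ~4.5 s), RMS 1."""
    t = np.arange(n_timepoints) * tr_seconds
    g = (t ** 3) * np.exp(-t / 1.5)
    rms = math.sqrt(float(np.mean(g ** 2)))
    if rms == 0.0:  # degenerate only for n_timepoints == 1, excluded by config
        raise SimConfigError("temporal profile degenerated to zero")
    return g / rms


def _ar1_noise(rng: np.random.Generator, shape: Tuple[int, ...], ar: float) -> np.ndarray:
    """AR(1) along the last axis with unit marginal variance."""
    eps = rng.standard_normal(shape)
    if ar == 0.0:
        return eps
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0]
    scale = math.sqrt(1.0 - ar * ar)
    for t in range(1, shape[-1]):
        out[..., t] = ar * out[..., t - 1] + scale * eps[..., t]
    return out


def _rowwise_pearson(rows: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``rows`` against ``ref``; 0 where degenerate."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    gc = ref - ref.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1) * (gc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc @ gc) / denom
    return np.where(denom > 0, r, 0.0)


def generate_dataset(config: SimConfig) -> Dataset:
    """Simulate a full cohort: trials, a trait table, and the ground truth.

    Deterministic given ``config.seed``.  The per-trial matrix is

        baseline_i + amp * v h(t)' + s_c * snr * sqrt(P) * gain_it * w g(t)' + noise,

    where ``w`` (unit norm, sparse) and ``g`` (RMS 1) are the planted condition
    axis and profile, ``s_c`` is +1 for imagined support and -1 for self-feel,
    and ``gain_it = 1 + a_i + eta_it`` carries participant and trial
    variability.  The sqrt(P) factor makes ``snr`` the ratio of planted-signal
    SD to (unit) noise SD over matrix entries.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    P, T = config.n_parcels, config.n_timepoints
    n_part = config.n_participants
    tpp = config.trials_per_participant
    n_total = n_part * tpp

    # planted structure
    signal_parcels = np.sort(rng.choice(P, size=config.n_signal_parcels, replace=False))
    w = np.zeros(P)
    w[signal_parcels] = rng.standard_normal(config.n_signal_parcels)
    w /= np.linalg.norm(w)
    if config.temporal_profile is not None:
        g = np.asarray(config.temporal_profile, dtype=float)
        g = g / math.sqrt(float(np.mean(g ** 2)))
    else:
        g = default_temporal_profile(T, config.tr_seconds)
    # condition-independent evoked response shared by every trial
    v = rng.standard_normal(P)
    v /= np.linalg.norm(v)
    h = np.cos(np.pi * np.arange(T) / max(T - 1, 1))
    h /= math.sqrt(float(np.mean(h ** 2)))

    # participants
    wave = np.where(np.arange(n_part) < (n_part + 1) // 2, 1, 2)
    age = rng.normal(18.4, 0.55, n_part)
    gain_intercept = rng.normal(0.0, config.gain_sd_between, n_part)
    rating_intercept = rng.normal(0.0, config.rating_intercept_sd, n_part)
    baselines = rng.normal(0.0, config.baseline_pattern_sd, (n_part, P))

    # trials
    part_idx = np.repeat(np.arange(n_part), tpp)
    is_support = rng.random(n_total) < config.p_support
    signs = np.where(is_support, 1.0, -1.0)
    gains = 1.0 + gain_intercept[part_idx] + rng.normal(0.0, config.gain_sd_within, n_total)
    baseline_neg = rng.choice([2, 3, 4, 5], size=n_total, p=[0.10, 0.25, 0.40, 0.25])
    provider = rng.random(n_total) < 0.5

    data = _ar1_noise(rng, (n_total, P, T), config.ar_coef)
    data += baselines[part_idx][:, :, None]
    data += config.common_response_amp * math.sqrt(P) * v[None, :, None] * h[None, None, :]
    amp = config.snr * math.sqrt(P) * gains * signs
    data += amp[:, None, None] * w[None, :, None] * g[None, None, :]

    # true signature expression: realized similarity of the planted-axis
    # projection with g(t); this is what ratings and traits are coupled to.
    projections = np.einsum("p,npt->nt", w, data)
    expression = _rowwise_pearson(projections, g)

    latent = (baseline_neg.astype(float) + rating_intercept[part_idx]
              - config.rating_slope * expression
              + rng.normal(0.0, config.rating_noise_sd, n_total))
    ratings = np.clip(np.rint(latent), 1, 5).astype(int)

    participant_ids = [f"P{i + 1:03d}" for i in range(n_part)]
    trials: List[TrialRecord] = []
    for n in range(n_total):
        i = part_idx[n]
        condition = CONDITION_SUPPORT if is_support[n] else CONDITION_SELF
        if condition == CONDITION_SELF:
            target = TARGET_SELF
        else:
            target = TARGET_SUPPORT_PROVIDER if provider[n] else TARGET_NON_PROVIDER
        trials.append(TrialRecord(
            participant_id=participant_ids[i],
            memory_id=f"{participant_ids[i]}_m{n - i * tpp:02d}",
            condition=condition,
            target_type=target,
            negativity_rating=int(ratings[n]),
            baseline_negativity=int(baseline_neg[n]),
            data=data[n],
        ))

    # participant mean expression over imagined-support trials (fallback: all)
    mean_expr = np.zeros(n_part)
    for i in range(n_part):
        mask = (part_idx == i) & is_support
        if not mask.any():
            mask = part_idx == i
        mean_expr[i] = expression[mask].mean()

    traits = pd.DataFrame({
        "participant_id": participant_ids,
        "wave": wave,
        "age": np.round(age, 2),
    })
    for name, slope in config.trait_slopes.items():
        base, noise_sd = TRAIT_SCALES.get(name, (0.0, 1.0))
        values = (base + slope * mean_expr
                  + config.trait_wave_effect * (wave - 1)
                  + rng.normal(0.0, noise_sd, n_part))
        if name == "support_count":
            values = np.clip(np.rint(values), 0, 6).astype(int)
        traits[name] = values

    truth = GroundTruth(
        spatial_pattern=w,
        temporal_profile=g,
        condition_signs=dict(CONDITION_SIGNS),
        rating_slope=config.rating_slope,
        trait_slopes=dict(config.trait_slopes),
        expression=expression,
        signal_parcels=signal_parcels,
        participant_mean_expression=pd.Series(mean_expr, index=participant_ids,
                                              name="mean_expression"),
        snr=config.snr,
    )
    return Dataset(trials=trials, traits=traits, truth=truth)


def generate_voxel_session(config: SimConfig, voxels_per_parcel: int = 1,
                           voxel_noise_sd: float = 0.0, gap_volumes: int = 10,
                           pad_volumes: int = 10) -> VoxelSession:
    """Simulate one participant's run at voxel resolution plus BIDS-style tables.

    Each parcel's planted time series is broadcast to ``voxels_per_parcel``
    voxels (independent voxel noise optional); global-signal and drift nuisance
    series are added to every voxel and recorded in the confound table, so the
    extraction front-end can remove exactly what was injected.  Events use
    onset/duration/trial_type columns with one 20 s epoch per trial.
    """
    import nibabel as nib

    if not isinstance(voxels_per_parcel, (int, np.integer)) or voxels_per_parcel < 1:
        raise SimConfigError(
            f"voxels_per_parcel must be a positive integer, got {voxels_per_parcel!r}")
    if voxel_noise_sd < 0:
        raise SimConfigError(f"voxel_noise_sd must be >= 0, got {voxel_noise_sd!r}")

    single = replace(config, n_participants=1)
    trials, _, _ = generate_dataset(single)
    P, T = config.n_parcels, config.n_timepoints
    n_trials = len(trials)
    n_vols = 2 * pad_volumes + n_trials * T + max(n_trials - 1, 0) * gap_volumes

    onset_volumes = [pad_volumes + i * (T + gap_volumes) for i in range(n_trials)]
    planted = np.zeros((n_vols, P))
    for vol0, trial in zip(onset_volumes, trials):
        planted[vol0:vol0 + T, :] = trial.data.T

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    global_signal = 0.3 * _ar1_noise(rng, (n_vols,), 0.5)
    drift_linear = np.linspace(-0.5, 0.5, n_vols)
    drift_cosine = 0.5 * np.cos(2.0 * np.pi * np.arange(n_vols) / n_vols)
    nuisance = global_signal + drift_linear + drift_cosine

    shape = (voxels_per_parcel, P, 1)
    vox = np.empty(shape + (n_vols,))
    vox[:] = planted.T[None, :, None, :]
    vox += nuisance[None, None, None, :]
    if voxel_noise_sd > 0:
        vox += voxel_noise_sd * rng.standard_normal(vox.shape)

    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    image = nib.Nifti1Image(vox, affine)
    image.header.set_zooms((3.0, 3.0, 3.0, config.tr_seconds))
    image.header.set_xyzt_units("mm", "sec")

    labels = np.broadcast_to(np.arange(1, P + 1)[None, :, None], shape)
    atlas = nib.Nifti1Image(np.ascontiguousarray(labels, dtype=np.int16), affine)

    confounds = pd.DataFrame({
        "global_signal": global_signal,
        "drift_linear": drift_linear,
        "drift_cosine": drift_cosine,
    })
    events = pd.DataFrame({
        "onset": [v * config.tr_seconds for v in onset_volumes],
        "duration": [T * config.tr_seconds] * n_trials,
        "trial_type": [t.condition for t in trials],
        "participant_id": [t.participant_id for t in trials],
        "memory_id": [t.memory_id for t in trials],
        "target_type": [t.target_type for t in trials],
        "negativity_rating": [t.negativity_rating for t in trials],
        "baseline_negativity": [t.baseline_negativity for t in trials],
    })
    return VoxelSession(image=image, atlas=atlas, confounds=confounds,
                        events=events, planted_series=planted, trials=trials)
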