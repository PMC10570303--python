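"""Parcel time-series extraction from 4D images with a fixed cleaning chain.

The chain is: confound regression -> linear detrend -> band-pass
(order-5 Butterworth, zero phase) -> per-parcel voxel mean -> per-parcel
z-score.  Averaging last preserves within-parcel voxel weighting; z-scoring
last makes "standardized" the final state of the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthetic import CONDITIONS, TrialRecord

__all__ = [
    "ExtractionError",
    "GridMismatchError",
    "ConfoundLengthError",
    "EmptyAtlasError",
    "EpochError",
    "UnknownConditionError",
    "ParcelTimeSeries",
    "clean_signals",
    "clean_and_extract",
    "epoch_trials",
]

_DEGENERATE_SD = 1e-12


class ExtractionError(ValueError):
    pass


class GridMismatchError(ExtractionError):
    """Functional image and atlas are not on the same voxel grid."""


class ConfoundLengthError(ExtractionError):
    """Confound table row count does not match the number of volumes."""


class EmptyAtlasError(ExtractionError):
    """Atlas volume contains no nonzero labels."""


class EpochError(ExtractionError):
    """An event's epoch does not fit within the run."""


class UnknownConditionError(ExtractionError):
    """An event carries a condition label the pipeline does not know."""


@dataclass
class ParcelTimeSeries:
    """Cleaned parcel signals: (n_volumes, n_parcels), columns sorted by label.

    After standardization every non-degenerate column has mean 0 and SD 1;
    columns with no variance are zeroed and flagged in ``degenerate``.
    """

    data: np.ndarray
    parcel_ids: np.ndarray
    tr_seconds: float
    degenerate: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


def regress_confounds(data: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize columns of ``data`` on the confounds (intercept included)."""
    design = np.column_stack([np.ones(len(data)), np.asarray(confounds, dtype=float)])
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def bandpass_filter(data: np.ndarray, band: Tuple[float, float], tr_seconds: float,
                    order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0."""
    low, high = band
    nyquist = 0.5 / tr_seconds
    if not (0.0 < low < high < nyquist):
        raise ExtractionError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist "
            f"({nyquist} Hz at TR = {tr_seconds} s)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=1.0 / tr_seconds,
                     output="sos")
    return sps.sosfiltfilt(sos, data, axis=0)


def zscore_columns(data: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Column-wise z-score; constant columns are zeroed and flagged."""
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    degenerate = sd < _DEGENERATE_SD
    safe_sd = np.where(degenerate, 1.0, sd)
    out = (data - mean) / safe_sd
    out[:, degenerate] = 0.0
    return out, degenerate


def clean_signals(data: np.ndarray, confounds: Optional[np.ndarray] = None,
                  detrend: bool = True,
                  band: Optional[Tuple[float, float]] = (0.01, 0.12),
                  tr_seconds: float = 1.0, standardize: bool = True,
                  filter_order: int = 5) -> np.ndarray:
    """Apply the cleaning chain to a (n_volumes, n_channels) array.

    Every step is optional so the same routine serves as the oracle for
    round-trip tests (e.g., raw parcel means with no cleaning at all).
    """
    out = np.array(data, dtype=float)
    if out.ndim != 2:
        raise ExtractionError(f"expected a 2-D (volumes x channels) array, got ndim={out.ndim}")
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if len(confounds) != len(out):
            raise ConfoundLengthError(
                f"confound table has {len(confounds)} rows for {len(out)} volumes")
        out = regress_confounds(out, confounds)
    if detrend:
        out = sps.detrend(out, axis=0, type="linear")
    if band is not None:
        out = bandpass_filter(out, band, tr_seconds, order=filter_order)
    if standardize:
        out, _ = zscore_columns(out)
    return out


def _as_array(image) -> np.ndarray:
    return np.asanyarray(image.dataobj) if hasattr(image, "dataobj") else np.asarray(image)


def clean_and_extract(image, atlas, confounds: Optional[pd.DataFrame] = None,
                      band: Optional[Tuple[float, float]] = (0.01, 0.12),
                      detrend: bool = True, standardize: bool = True,
                      tr_seconds: Optional[float] = None,
                      filter_order: int = 5) -> ParcelTimeSeries:
    """Clean voxel signals and average them into per-parcel time series.

    ``image`` is a 4-D NIfTI image (or array); ``atlas`` an integer label image
    on the same grid (label 0 = background).  Returns one column per label
    present, sorted by label value.
    """
    img_data = np.asarray(_as_array(image), dtype=float)
    atlas_data = np.asarray(_as_array(atlas))
    if img_data.ndim != 4:
        raise ExtractionError(f"functional image must be 4-D, got shape {img_data.shape}")
    if atlas_data.shape != img_data.shape[:3]:
        raise GridMismatchError(
            f"atlas grid {atlas_data.shape} does not match image grid {img_data.shape[:3]}")
    labels = np.unique(atlas_data)
    labels = labels[labels > 0].astype(int)
    if labels.size == 0:
        raise EmptyAtlasError("atlas contains no nonzero labels")

    n_vols = img_data.shape[3]
    if tr_seconds is None:
        zooms = getattr(getattr(image, "header", None), "get_zooms", lambda: ())()
        tr_seconds = float(zooms[3]) if len(zooms) >= 4 and zooms[3] > 0 else 1.0

    conf_values = None
    if confounds is not None:
        conf_values = np.asarray(confounds, dtype=float)
        if conf_values.ndim == 1:
            conf_values = conf_values[:, None]
        if len(conf_values) != n_vols:
            raise ConfoundLengthError(
                f"confound table has {len(conf_values)} rows for {n_vols} volumes")

    flat_atlas = atlas_data.reshape(-1)
    in_brain = flat_atlas > 0
    voxels = img_data.reshape(-1, n_vols)[in_brain].T  # (n_vols, n_voxels)
    voxel_labels = flat_atlas[in_brain]

    cleaned = clean_signals(voxels, confounds=conf_values, detrend=detrend,
                            band=band, tr_seconds=tr_seconds, standardize=False,
                            filter_order=filter_order)

    parcel_means = np.empty((n_vols, labels.size))
    for j, label in enumerate(labels):
        parcel_means[:, j] = cleaned[:, voxel_labels == label].mean(axis=1)

    if standardize:
        parcel_means, degenerate = zscore_columns(parcel_means)
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} parcel(s) had zero variance and were zeroed",
                RuntimeWarning, stacklevel=2)
    else:
        degenerate = np.zeros(labels.size, dtype=bool)

    return ParcelTimeSeries(data=parcel_means, parcel_ids=labels,
                            tr_seconds=float(tr_seconds), degenerate=degenerate)


def epoch_trials(series: ParcelTimeSeries, events: pd.DataFrame,
                 n_timepoints: int) -> List[TrialRecord]:
    """Cut per-trial parcel x time matrices out of a run.

    Each trial starts at the volume nearest the event onset (0-based,
    ``round(onset / TR)``) and spans exactly ``n_timepoints`` consecutive
    volumes; longer event durations are truncated to the first
    ``n_timepoints`` volumes.
    """
    if "trial_type" in events.columns:
        condition_col = "trial_type"
    elif "condition" in events.columns:
        condition_col = "condition"
    else:
        raise ExtractionError("events table needs a 'trial_type' or 'condition' column")
    if "onset" not in events.columns:
        raise ExtractionError("events table needs an 'onset' column (seconds)")

    trials: List[TrialRecord] = []
    for row in events.itertuples(index=False):
        onset = float(getattr(row, "onset"))
        condition = str(getattr(row, condition_col))
        if condition not in CONDITIONS:
            raise UnknownConditionError(
                f"unknown condition {condition!r} at onset {onset} s "
                f"(expected one of {CONDITIONS})")
        vol0 = int(round(onset / series.tr_seconds))
        if vol0 < 0 or vol0 + n_timepoints > series.n_volumes:
            raise EpochError(
                f"event at onset {onset} s needs volumes [{vol0}, "
                f"{vol0 + n_timepoints}) but the run has {series.n_volumes} volumes")
        data = series.data[vol0:vol0 + n_timepoints, :].T.copy()
        trials.append(TrialRecord(
            participant_id=str(getattr(row, "participant_id", "unknown")),
            memory_id=str(getattr(row, "memory_id", f"onset_{onset:g}")),
            condition=condition,
            target_type=str(getattr(row, "target_type", "unknown")),
            negativity_rating=int(getattr(row, "negativity_rating", 3)),
            baseline_negativity=int(getattr(row, "baseline_negativity", 3)),
            data=data,
        ))
    return trials
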