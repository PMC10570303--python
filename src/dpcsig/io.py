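"""Deterministic on-disk formats for datasets, models, and results.

Trial metadata, traits, similarity tables and parcel statistics are TSV;
ground-truth and model vectors are .npy arrays next to a JSON metadata file.
All writers are byte-deterministic given identical inputs (no timestamps,
sorted JSON keys), which is what makes seeded CLI replay reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .dpca import DpcaModel
from .synthetic import Dataset, GroundTruth, TrialRecord

__all__ = [
    "save_dataset", "load_dataset", "save_model", "load_model",
    "save_table", "load_table",
]


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def save_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def trials_to_frames(trials: List[TrialRecord]) -> Tuple[pd.DataFrame, np.ndarray]:
    meta = pd.DataFrame({
        "participant_id": [t.participant_id for t in trials],
        "memory_id": [t.memory_id for t in trials],
        "condition": [t.condition for t in trials],
        "target_type": [t.target_type for t in trials],
        "negativity_rating": [t.negativity_rating for t in trials],
        "baseline_negativity": [t.baseline_negativity for t in trials],
    })
    data = np.stack([t.data for t in trials])
    return meta, data


def trials_from_frames(meta: pd.DataFrame, data: np.ndarray) -> List[TrialRecord]:
    if len(meta) != len(data):
        raise ValueError(f"metadata rows ({len(meta)}) != data stack ({len(data)})")
    return [TrialRecord(participant_id=str(r.participant_id),
                        memory_id=str(r.memory_id), condition=str(r.condition),
                        target_type=str(r.target_type),
                        negativity_rating=int(r.negativity_rating),
                        baseline_negativity=int(r.baseline_negativity),
                        data=data[i])
            for i, r in enumerate(meta.itertuples(index=False))]


def save_dataset(directory, trials: List[TrialRecord],
                 traits: Optional[pd.DataFrame] = None,
                 truth: Optional[GroundTruth] = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta, data = trials_to_frames(trials)
    save_table(directory / "trials.tsv", meta)
    np.save(directory / "trials_data.npy", data)
    if traits is not None:
        save_table(directory / "traits.tsv", traits)
    if truth is not None:
        np.save(directory / "truth_spatial_pattern.npy", truth.spatial_pattern)
        np.save(directory / "truth_temporal_profile.npy", truth.temporal_profile)
        np.save(directory / "truth_expression.npy", truth.expression)
        np.save(directory / "truth_signal_parcels.npy", truth.signal_parcels)
        _write_json(directory / "truth.json", {
            "condition_signs": truth.condition_signs,
            "rating_slope": truth.rating_slope,
            "trait_slopes": truth.trait_slopes,
            "snr": truth.snr,
            "participant_mean_expression": {
                k: float(v) for k, v in truth.participant_mean_expression.items()},
        })


def load_dataset(directory) -> Dataset:
    directory = Path(directory)
    meta = load_table(directory / "trials.tsv")
    data = np.load(directory / "trials_data.npy")
    trials = trials_from_frames(meta, data)
    traits_path = directory / "traits.tsv"
    traits = load_table(traits_path) if traits_path.exists() else None
    truth = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        mean_expr = pd.Series(payload["participant_mean_expression"],
                              name="mean_expression")
        truth = GroundTruth(
            spatial_pattern=np.load(directory / "truth_spatial_pattern.npy"),
            temporal_profile=np.load(directory / "truth_temporal_profile.npy"),
            condition_signs=payload["condition_signs"],
            rating_slope=payload["rating_slope"],
            trait_slopes=payload["trait_slopes"],
            expression=np.load(directory / "truth_expression.npy"),
            signal_parcels=np.load(directory / "truth_signal_parcels.npy"),
            participant_mean_expression=mean_expr,
            snr=payload["snr"],
        )
    return Dataset(trials=trials, traits=traits, truth=truth)


def save_model(directory, model: DpcaModel) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "decoder.npy", model.decoder)
    np.save(directory / "encoder.npy", model.encoder)
    np.save(directory / "grand_mean.npy", model.grand_mean)
    _write_json(directory / "model.json", {
        "lambda_reg": model.lambda_reg,
        "variance_explained": model.variance_explained,
        "objective": model.objective,
        "conditions": list(model.conditions),
        "sign_convention": model.sign_convention,
        "oriented": model.oriented,
    })


def load_model(directory) -> DpcaModel:
    directory = Path(directory)
    payload = json.loads((directory / "model.json").read_text())
    return DpcaModel(
        decoder=np.load(directory / "decoder.npy"),
        encoder=np.load(directory / "encoder.npy"),
        grand_mean=np.load(directory / "grand_mean.npy"),
        lambda_reg=payload["lambda_reg"],
        variance_explained=payload["variance_explained"],
        objective=payload["objective"],
        conditions=tuple(payload["conditions"]),
        sign_convention=payload["sign_convention"],
        oriented=payload["oriented"],
    )
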