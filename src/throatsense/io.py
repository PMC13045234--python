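"""Readers and writers: WAV recordings, CSV manifests, HDF5 feature stores.

Recordings are persisted as 16-bit PCM WAV at 4000 Hz with the 12-bit
ADC codes mapped linearly onto the int16 range; feature matrices live in
one HDF5 file under /features/<recording_id> with a mirrored label table.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .recognizer import FeatureDataset
from .synthgen import EMOTIONS, SAMPLING_RATE, ThroatRecording
from .telemetry import ADC_MIDPOINT

__all__ = [
    "MANIFEST_COLUMNS",
    "write_wav",
    "read_wav",
    "write_manifest",
    "read_manifest",
    "write_feature_store",
    "read_feature_store",
    "write_report_json",
]

MANIFEST_COLUMNS = ["recording_id", "subject_id", "emotion", "sentence_id",
                    "repetition", "seed"]

_WAV_SCALE = 16  # 12-bit codes, sign-centered, shifted into int16 range


def write_wav(path, recording: ThroatRecording) -> None:
    pcm = ((recording.samples - ADC_MIDPOINT) * _WAV_SCALE).astype(np.int16)
    wavfile.write(str(path), recording.sampling_rate, pcm)


def read_wav(path, subject_id=0, emotion="Neutral", sentence_id=0, repetition=0,
             seed=0) -> ThroatRecording:
    rate, pcm = wavfile.read(str(path))
    if rate != SAMPLING_RATE:
        raise ValueError(f"expected {SAMPLING_RATE} Hz WAV, got {rate}")
    codes = (pcm.astype(np.int32) // _WAV_SCALE) + ADC_MIDPOINT
    return ThroatRecording(
        samples=np.clip(codes, 0, 4095), sampling_rate=rate, subject_id=subject_id,
        emotion=emotion, sentence_id=sentence_id, repetition=repetition, seed=seed,
    )


def write_manifest(path, manifest: pd.DataFrame) -> None:
    _validate_manifest(manifest)
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    _validate_manifest(manifest)
    return manifest


def _validate_manifest(manifest: pd.DataFrame) -> None:
    for col in MANIFEST_COLUMNS:
        if col not in manifest.columns:
            raise ValueError(f"manifest missing required column: {col!r}")
    if manifest["recording_id"].duplicated().any():
        dup = manifest.loc[manifest["recording_id"].duplicated(), "recording_id"].iloc[0]
        raise ValueError(f"duplicate recording id in manifest: {dup!r}")


def write_feature_store(path, dataset: FeatureDataset, manifest: pd.DataFrame) -> None:
    """One HDF5 file: /features/<id> datasets plus the label table."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("features")
        for rid, mat in zip(dataset.recording_ids, dataset.features):
            grp.create_dataset(rid, data=mat.astype(np.float32))
        lab = f.create_group("labels")
        lab.create_dataset(
            "recording_id",
            data=np.array(dataset.recording_ids, dtype=h5py.string_dtype()),
        )
        lab.create_dataset("emotion", data=dataset.emotion_labels)
        lab.create_dataset("sentence_id", data=dataset.text_labels)
        lab.create_dataset("subject_id", data=dataset.subject_ids)
        f.attrs["manifest_csv"] = manifest.to_csv(index=False)


def read_feature_store(path):
    """Returns (FeatureDataset, manifest)."""
    with h5py.File(path, "r") as f:
        rids = [r.decode() for r in f["labels/recording_id"][...]]
        feats = np.stack([f["features"][r][...] for r in rids])
        ds = FeatureDataset(
            features=feats,
            emotion_labels=f["labels/emotion"][...],
            text_labels=f["labels/sentence_id"][...],
            subject_ids=f["labels/subject_id"][...],
            recording_ids=rids,
        )
        from io import StringIO

        manifest = pd.read_csv(StringIO(f.attrs["manifest_csv"]))
    return ds, manifest


def write_report_json(path, report) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def build_feature_dataset(recordings, manifest: pd.DataFrame) -> FeatureDataset:
    """Featurize a generated corpus into a stacked dataset."""
    from .features import featurize_recording

    emo_idx = {e: i for i, e in enumerate(EMOTIONS)}
    feats, ye, yt, subj, rids = [], [], [], [], []
    for rec, rid in zip(recordings, manifest["recording_id"]):
        fm = featurize_recording(rec)
        feats.append(fm.values.astype(np.float32))
        ye.append(emo_idx[rec.emotion])
        yt.append(rec.sentence_id)
        subj.append(rec.subject_id)
        rids.append(rid)
    return FeatureDataset(
        features=np.stack(feats), emotion_labels=ye, text_labels=yt,
        subject_ids=subj, recording_ids=rids,
    )
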