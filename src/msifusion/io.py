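"""Readers and writers for stimuli, datasets and fitted transforms.

Visual prototypes go to PNG/PGM, auditory prototypes to 16-bit WAV, and
labeled stimulus sets to an ``.npz`` archive with a JSON sidecar carrying
the generation metadata (seed, variance, attenuation). Loaded external
audio is fitted to the modality's raw dimension by tail truncation or
tail zero-padding.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.io import wavfile

from .channel import FeatureTransform
from .stimuli import LabeledStimulusSet

__all__ = [
    "save_image",
    "load_image",
    "save_wav",
    "load_wav",
    "fit_length",
    "save_dataset",
    "load_dataset",
    "save_transform",
    "load_transform",
]


def save_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a binary image as PNG or PGM (by file extension)."""
    path = Path(path)
    arr = (np.asarray(image) > 0.5).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)
    return path


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as a {0,1} array (threshold at mid-gray)."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    return (arr >= 127.5).astype(float)


def save_wav(waveform: np.ndarray, sample_rate: int, path: str | Path) -> Path:
    """Write a [-1, 1] waveform as 16-bit PCM WAV."""
    path = Path(path)
    clipped = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (clipped * 32767).astype(np.int16))
    return path


def load_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file as a float waveform in [-1, 1] plus its rate."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), int(rate)


def fit_length(signal: np.ndarray, d: int) -> np.ndarray:
    """Truncate or zero-pad the signal tail to exactly d samples."""
    x = np.asarray(signal, dtype=float).ravel()
    if len(x) >= d:
        return x[:d].copy()
    return np.concatenate([x, np.zeros(d - len(x))])


def save_dataset(dataset: LabeledStimulusSet, path: str | Path) -> Path:
    """Write a stimulus set as NPZ plus a JSON metadata sidecar."""
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, signals=dataset.signals, labels=dataset.labels)
    meta = {
        "modality_id": dataset.modality_id,
        "generation_seed": dataset.generation_seed,
        "noise_variance": dataset.noise_variance,
        "attenuation": dataset.attenuation,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_dataset(path: str | Path) -> LabeledStimulusSet:
    path = Path(path).with_suffix(".npz")
    arrays = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return LabeledStimulusSet(
        modality_id=meta["modality_id"],
        signals=arrays["signals"],
        labels=arrays["labels"],
        generation_seed=meta["generation_seed"],
        noise_variance=meta["noise_variance"],
        attenuation=meta["attenuation"],
    )


def save_transform(transform: FeatureTransform, path: str | Path) -> Path:
    """Serialize a fitted feature transform as JSON."""
    path = Path(path)
    payload = {
        "raw_dim": transform.raw_dim,
        "selected_indices": np.asarray(transform.selected_indices).tolist(),
        "slope": transform.slope,
        "intercept": transform.intercept,
        "interval": list(transform.interval),
        "fitted_min": transform.fitted_min,
        "fitted_max": transform.fitted_max,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_transform(path: str | Path) -> FeatureTransform:
    payload = json.loads(Path(path).read_text())
    return FeatureTransform(
        raw_dim=payload["raw_dim"],
        selected_indices=np.asarray(payload["selected_indices"], dtype=int),
        slope=payload["slope"],
        intercept=payload["intercept"],
        interval=tuple(payload["interval"]),
        fitted_min=payload["fitted_min"],
        fitted_max=payload["fitted_max"],
    )
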