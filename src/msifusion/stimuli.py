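"""Synthetic audiovisual stimulus generation.

Produces class-distinct prototype stimuli for a K-class digit recognition
task in two modalities — binary digit-glyph images (visual) and procedurally
synthesized waveforms standing in for spoken digits (auditory) — together
with noisy, attenuated labeled datasets built from those prototypes.

Each noisy stimulus is ``alpha * prototype + N(0, sigma^2 I)``: a scalar
attenuation ``alpha`` in [0, 1] models stimulus effectiveness (1 = full
strength, 0 = absent), and additive white Gaussian noise models external
environmental uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Prototype",
    "LabeledStimulusSet",
    "make_visual_prototypes",
    "make_auditory_prototypes",
    "vectorize_image",
    "generate_dataset",
]


# 5x7 dot-matrix glyphs for the digits 0-9. Deterministic and
# resolution-independent: rendering scales these by nearest neighbour.
_DIGIT_GLYPHS = [
    "01110 10001 10011 10101 11001 10001 01110",  # 0
    "00100 01100 00100 00100 00100 00100 01110",  # 1
    "01110 10001 00001 00010 00100 01000 11111",  # 2
    "11111 00010 00100 00010 00001 10001 01110",  # 3
    "00010 00110 01010 10010 11111 00010 00010",  # 4
    "11111 10000 11110 00001 00001 10001 01110",  # 5
    "00110 01000 10000 11110 10001 10001 01110",  # 6
    "11111 00001 00010 00100 01000 01000 01000",  # 7
    "01110 10001 10001 01110 10001 10001 01110",  # 8
    "01110 10001 10001 01111 00001 00010 01100",  # 9
]


@dataclass(frozen=True)
class Prototype:
    """A single noise-free class prototype for one modality.

    ``signal`` is the raw stimulus: a 2-D {0,1} array for images, a 1-D
    float array with amplitudes in [-1, 1] for waveforms.
    """

    class_index: int
    modality_id: int
    signal: np.ndarray = field(repr=False)

    @property
    def vector(self) -> np.ndarray:
        """Row-major flattened view of the signal."""
        return np.asarray(self.signal, dtype=float).ravel(order="C")


@dataclass(frozen=True)
class LabeledStimulusSet:
    """Labeled raw stimuli for one modality.

    ``signals`` has shape (n, d); ``labels`` holds 0-based class indices.
    The generating seed, noise variance and attenuation are recorded so
    the set is reproducible and self-describing.
    """

    modality_id: int
    signals: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    generation_seed: int
    noise_variance: float
    attenuation: float

    def __post_init__(self) -> None:
        if self.signals.shape[0] != self.labels.shape[0]:
            raise ValueError("signals and labels length mismatch")

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1


def _render_glyph(bitmap: str, height: int, width: int) -> np.ndarray:
    rows = bitmap.split()
    gh, gw = len(rows), len(rows[0])
    grid = np.array([[int(ch) for ch in r] for r in rows], dtype=float)
    # nearest-neighbour upsample onto the target resolution
    ri = np.minimum((np.arange(height) * gh) // height, gh - 1)
    ci = np.minimum((np.arange(width) * gw) // width, gw - 1)
    img = grid[np.ix_(ri, ci)]
    return (img >= 0.5).astype(float)


def make_visual_prototypes(
    n_classes: int, height: int = 64, width: int = 64
) -> list[Prototype]:
    """Render the digit glyphs 0..n_classes-1 as binary images.

    Fully deterministic: the same arguments always produce identical
    arrays. Raises if the resolution is too coarse to keep the rendered
    glyphs pairwise distinct.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_classes > len(_DIGIT_GLYPHS):
        raise ValueError(f"only {len(_DIGIT_GLYPHS)} digit glyphs available")
    if height < 8 or width < 8:
        raise ValueError("height and width must be >= 8")
    protos = [
        Prototype(k, 1, _render_glyph(_DIGIT_GLYPHS[k], height, width))
        for k in range(n_classes)
    ]
    flat = np.stack([p.vector for p in protos])
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            if np.array_equal(flat[i], flat[j]):
                raise ValueError(
                    f"resolution {height}x{width} cannot distinguish glyphs "
                    f"{i} and {j}"
                )
    return protos


def make_auditory_prototypes(
    n_classes: int,
    sample_rate: float = 8000.0,
    n_samples: int = 4000,
    prototype_seed: int = 0,
) -> list[Prototype]:
    """Synthesize class-unique waveform prototypes.

    Classes are organized in pairs sharing a spectral band: band-mates
    (classes k and k + n_bands) share the same fundamental and second
    harmonic but differ in a class-unique component (an extra harmonic
    and an up- versus down-sweeping chirp). This emulates the
    concentrated, pairwise confusion structure of real spoken digits
    (e.g., "five"/"nine"), where acoustically similar words share most
    of their spectral energy yet remain separable; across bands the
    prototypes are nearly orthogonal. A Hann envelope shapes each
    waveform. Shared-component phases are drawn per band and unique
    phases per class from ``prototype_seed``, so output is deterministic
    given identical arguments.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")
    n_bands = (n_classes + 1) // 2
    f_base, f_step = 300.0, 150.0
    top = (f_base + f_step * (n_bands - 1)) * 2.7  # highest component used
    if top >= 0.45 * sample_rate:
        raise ValueError(
            f"{n_classes} distinct spectral recipes do not fit below the "
            f"Nyquist frequency at {sample_rate} Hz"
        )
    t = np.arange(n_samples) / sample_rate
    dur = t[-1]
    envelope = np.hanning(n_samples)
    protos = []
    for k in range(n_classes):
        band, variant = k % n_bands, k // n_bands
        band_rng = np.random.default_rng([prototype_seed, band])
        shared_phases = band_rng.uniform(0, 2 * np.pi, size=2)
        rng = np.random.default_rng([prototype_seed, 1000 + k])
        own_phases = rng.uniform(0, 2 * np.pi, size=2)
        f0 = f_base + f_step * band
        harm = 1.6 if variant == 0 else 2.7  # class-unique harmonic ratio
        sweep = 0.3 if variant == 0 else -0.3  # chirp direction
        wave = (
            1.0 * np.sin(2 * np.pi * f0 * t + shared_phases[0])
            + 0.5 * np.sin(2 * np.pi * 2.0 * f0 * t + shared_phases[1])
            + 0.45 * np.sin(2 * np.pi * harm * f0 * t + own_phases[0])
            + 0.35
            * np.sin(
                2 * np.pi * f0 * (t + 0.5 * sweep * t**2 / dur) + own_phases[1]
            )
        )
        wave *= envelope
        wave *= 0.9 / np.max(np.abs(wave))
        protos.append(Prototype(k, 2, wave))
    return protos


def vectorize_image(image: np.ndarray) -> np.ndarray:
    """Concatenate the rows of a 2-D array into one vector (row-major)."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a nonempty 2-D array")
    return arr.ravel(order="C")


def _prototype_matrix(prototypes: list[Prototype]) -> np.ndarray:
    vecs = [p.vector for p in prototypes]
    d = {v.shape[0] for v in vecs}
    if len(d) != 1:
        raise ValueError("prototypes have inconsistent lengths")
    return np.stack(vecs)


def generate_dataset(
    prototypes: list[Prototype],
    n_per_class: int,
    noise_variance: float,
    attenuation: float,
    seed: int,
    labels: np.ndarray | None = None,
) -> LabeledStimulusSet:
    """Draw a labeled noisy/attenuated stimulus set from prototypes.

    Each stimulus is ``attenuation * prototype + N(0, noise_variance * I)``.
    By default every class appears exactly ``n_per_class`` times, grouped
    by class; passing an explicit ``labels`` array instead fixes the class
    sequence (used to build semantically congruent multimodal sets that
    share one label ordering across modalities).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if noise_variance < 0:
        raise ValueError("noise_variance must be nonnegative")
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError("attenuation must lie in [0, 1]")
    proto = _prototype_matrix(prototypes)
    n_classes, d = proto.shape
    if labels is None:
        labels = np.repeat(np.arange(n_classes), n_per_class)
    else:
        labels = np.asarray(labels, dtype=int)
        if labels.min() < 0 or labels.max() >= n_classes:
            raise ValueError("labels outside prototype class range")
    rng = np.random.default_rng(seed)
    signals = attenuation * proto[labels]
    if noise_variance > 0:
        signals = signals + rng.normal(
            0.0, np.sqrt(noise_variance), size=signals.shape
        )
    return LabeledStimulusSet(
        modality_id=prototypes[0].modality_id,
        signals=signals,
        labels=labels,
        generation_seed=int(seed),
        noise_variance=float(noise_variance),
        attenuation=float(attenuation),
    )
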