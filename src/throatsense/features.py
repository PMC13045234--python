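"""Feature extraction: the 40x128 MFCC stack, Mel spectrograms, prosody.

Row layout of the feature matrix: rows 0-12 are cepstral coefficients
c1..c13 (c0 excluded), rows 13-25 their first differentials, rows 26-38
the second differentials, and row 39 the log frame energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft

from .preprocess import (
    FrameSequence,
    PreprocessConfig,
    preprocess_recording,
    voiced_regions,
)
from .telemetry import adc_to_normalized

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "MelSpectrogram",
    "ProsodicDescriptors",
    "mel_filterbank",
    "mfcc_stack",
    "mel_spectrogram",
    "prosodic_descriptors",
    "featurize_recording",
]

ENERGY_EPS = 1e-10  # floor applied before every log
N_MEL = 40
N_CEPSTRA = 13
N_FRAMES = 128
N_ROWS = 3 * N_CEPSTRA + 1  # 40
PAUSE_MIN_S = 0.200  # silence >= 200 ms counts as a pause


@dataclass(frozen=True)
class FeatureConfig:
    n_mels: int = N_MEL
    n_cepstra: int = N_CEPSTRA
    n_fft: int = 256
    sampling_rate: int = 4000
    fmin: float = 0.0
    fmax: float = 2000.0  # Nyquist of the 4 ksps chain
    delta_window: int = 2


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (40, 128)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_ROWS, N_FRAMES):
            raise ValueError(
                f"feature matrix must be ({N_ROWS}, {N_FRAMES}), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def mfcc(self) -> np.ndarray:
        return self.values[0:N_CEPSTRA]

    @property
    def delta(self) -> np.ndarray:
        return self.values[N_CEPSTRA : 2 * N_CEPSTRA]

    @property
    def delta2(self) -> np.ndarray:
        return self.values[2 * N_CEPSTRA : 3 * N_CEPSTRA]

    @property
    def log_energy(self) -> np.ndarray:
        return self.values[N_ROWS - 1]


@dataclass
class MelSpectrogram:
    values: np.ndarray  # (40, 128), nonnegative filterbank energies
    mel_band_edges: np.ndarray  # Hz, length n_mels + 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("mel energies must be nonnegative")


@dataclass
class ProsodicDescriptors:
    """Waveform-level statistics characterizing emotional prosody."""

    speech_rate: float  # voiced burst groups per minute
    pause_rate: float  # silences >= 200 ms per minute
    mean_norm_amplitude: float
    peak_to_peak_norm: float
    energy_mean: float  # mean of per-frame mean |x| over voiced frames
    energy_sd: float
    delta_mfcc_mean: float


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(config: FeatureConfig = FeatureConfig()):
    """Triangular mel filters. Returns (weights (n_mels, n_fft//2+1), edges Hz)."""
    n_bins = config.n_fft // 2 + 1
    mel_edges = np.linspace(
        _hz_to_mel(config.fmin), _hz_to_mel(config.fmax), config.n_mels + 2
    )
    hz_edges = _mel_to_hz(mel_edges)
    bin_freqs = np.arange(n_bins) * config.sampling_rate / config.n_fft
    weights = np.zeros((config.n_mels, n_bins))
    for i in range(config.n_mels):
        lo, mid, hi = hz_edges[i], hz_edges[i + 1], hz_edges[i + 2]
        up = (bin_freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - mid, 1e-12)
        weights[i] = np.clip(np.minimum(up, down), 0.0, None)
    return weights, hz_edges


def _mel_energies(frames: np.ndarray, config: FeatureConfig) -> np.ndarray:
    weights, _ = mel_filterbank(config)
    spectra = np.abs(rfft(frames, n=config.n_fft, axis=1)) ** 2
    return spectra @ weights.T  # (n_frames, n_mels)


def _delta(c: np.ndarray, window: int) -> np.ndarray:
    """Regression delta over +-window frames, edge frames replicated."""
    n = np.arange(1, window + 1)
    denom = 2.0 * np.sum(n**2)
    padded = np.pad(c, ((window, window), (0, 0)), mode="edge")
    out = np.zeros_like(c)
    for k in n:
        out += k * (padded[window + k : padded.shape[0] - window + k]
                    - padded[window - k : padded.shape[0] - window - k])[: c.shape[0]]
    return out / denom


def mfcc_stack(frames: FrameSequence, config: FeatureConfig = FeatureConfig()) -> FeatureMatrix:
    """Mel-cepstral feature matrix: c1..c13, deltas, delta-deltas, log energy."""
    f = np.asarray(frames.frames, dtype=np.float64)
    if f.shape[0] != N_FRAMES:
        raise ValueError(f"expected exactly {N_FRAMES} frames, got {f.shape[0]}")
    mel = np.maximum(_mel_energies(f, config), ENERGY_EPS)
    cep = dct(np.log(mel), type=2, norm="ortho", axis=1)
    c = cep[:, 1 : config.n_cepstra + 1]  # c1..c13, c0 dropped
    d1 = _delta(c, config.delta_window)
    d2 = _delta(d1, config.delta_window)
    log_e = np.log(np.maximum(np.sum(f**2, axis=1), ENERGY_EPS))
    values = np.vstack([c.T, d1.T, d2.T, log_e[None, :]])
    return FeatureMatrix(values=values)


def mel_spectrogram(
    frames: FrameSequence, config: FeatureConfig = FeatureConfig()
) -> MelSpectrogram:
    """Nonnegative 40x128 matrix of mel filterbank energies."""
    f = np.asarray(frames.frames, dtype=np.float64)
    if f.shape[0] != N_FRAMES:
        raise ValueError(f"expected exactly {N_FRAMES} frames, got {f.shape[0]}")
    mel = np.maximum(_mel_energies(f, config), ENERGY_EPS)
    _, edges = mel_filterbank(config)
    return MelSpectrogram(values=mel.T, mel_band_edges=edges)


def _normalized_samples(rec) -> np.ndarray:
    samples = rec.samples if hasattr(rec, "samples") else rec
    return adc_to_normalized(np.asarray(samples))


def prosodic_descriptors(
    rec,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    feature_config: FeatureConfig = FeatureConfig(),
    with_delta_mfcc: bool = True,
) -> ProsodicDescriptors:
    """Measure the waveform statistics used to characterize each emotion.

    ``rec`` may be a ThroatRecording or a raw array of 12-bit ADC codes.
    Samples are normalized to [-1, 1] about the ADC midpoint; bursts and
    pauses are located with the endpoint detector's region segmentation.
    An all-silence recording yields zeros throughout.
    """
    x = _normalized_samples(rec)
    if x.size == 0:
        raise ValueError("recording is empty")
    fs = preprocess_config.sampling_rate
    minutes = x.size / fs / 60.0
    regions = voiced_regions(x, preprocess_config)
    if not regions:
        return ProsodicDescriptors(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    speech_rate = len(regions) / minutes
    gaps = [
        (regions[i + 1][0] - regions[i][1]) / fs for i in range(len(regions) - 1)
    ]
    pause_rate = sum(1 for g in gaps if g >= PAUSE_MIN_S) / minutes

    voiced = np.concatenate([x[s:e] for s, e in regions])
    mean_amp = float(np.mean(np.abs(voiced)))
    p2p = float(voiced.max() - voiced.min())

    # frame-level energy = per-frame mean |x| inside voiced regions
    flen = preprocess_config.analysis_frame
    hop = preprocess_config.analysis_hop
    energies = []
    for s, e in regions:
        seg = x[s:e]
        n = 1 + max(0, (seg.size - flen)) // hop
        for i in range(n):
            energies.append(np.mean(np.abs(seg[i * hop : i * hop + flen])))
    energies = np.asarray(energies)
    e_mean = float(energies.mean()) if energies.size else 0.0
    e_sd = float(energies.std(ddof=0)) if energies.size else 0.0

    d_mfcc = 0.0
    if with_delta_mfcc:
        try:
            frames = preprocess_recording(x, preprocess_config)
            fm = mfcc_stack(frames, feature_config)
            d_mfcc = float(np.mean(np.abs(fm.delta)))
        except ValueError:
            d_mfcc = 0.0

    return ProsodicDescriptors(
        speech_rate=speech_rate,
        pause_rate=pause_rate,
        mean_norm_amplitude=mean_amp,
        peak_to_peak_norm=p2p,
        energy_mean=e_mean,
        energy_sd=e_sd,
        delta_mfcc_mean=d_mfcc,
    )


def featurize_recording(
    rec,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    feature_config: FeatureConfig = FeatureConfig(),
) -> FeatureMatrix:
    """Raw recording → conditioned frames → 40x128 feature matrix."""
    x = _normalized_samples(rec)
    frames = preprocess_recording(x, preprocess_config)
    fm = mfcc_stack(frames, feature_config)
    if hasattr(rec, "subject_id"):
        fm.metadata = {
            "subject_id": rec.subject_id,
            "emotion": rec.emotion,
            "sentence_id": rec.sentence_id,
            "repetition": rec.repetition,
        }
    return fm
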