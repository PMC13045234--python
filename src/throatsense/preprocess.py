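"""Waveform conditioning: pre-emphasis, endpoint detection, framing, windowing.

A raw recording is turned into exactly 128 overlapping Hamming-windowed
frames of its voiced region. Endpoint detection uses the classical
double-threshold short-time energy + zero-crossing-rate scheme with
hysteresis, calibrated on the assumed-silent first 100 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hamming

__all__ = [
    "PreprocessConfig",
    "FrameSequence",
    "pre_emphasis",
    "detect_endpoints",
    "voiced_regions",
    "frame_and_window",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    preemphasis_alpha: float = 0.98
    n_frames: int = 128
    frame_length: int = 128  # 32 ms at 4 kHz
    sampling_rate: int = 4000
    # endpoint detector settings
    analysis_frame_ms: float = 20.0
    analysis_hop_ms: float = 10.0
    calibration_ms: float = 100.0  # assumed-silent prefix
    energy_high_factor: float = 8.0  # × noise RMS → enter speech
    energy_low_factor: float = 3.0  # × noise RMS → extend speech (hysteresis)
    energy_floor_frac: float = 0.05  # of peak frame RMS, guards tiny noise floors
    zcr_threshold: float = 0.95  # crossings per sample; above → treat as noise
    min_voiced_ms: float = 40.0
    min_speech_rms: float = 0.02  # absolute floor for normalized-amplitude traces

    def __post_init__(self) -> None:
        if not 0.0 < self.preemphasis_alpha < 1.0:
            raise ValueError(f"preemphasis_alpha must be in (0,1), got {self.preemphasis_alpha}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def analysis_frame(self) -> int:
        return int(round(self.analysis_frame_ms * self.sampling_rate / 1000.0))

    @property
    def analysis_hop(self) -> int:
        return int(round(self.analysis_hop_ms * self.sampling_rate / 1000.0))


@dataclass
class FrameSequence:
    """Exactly ``n_frames`` overlapping windowed frames of the voiced span."""

    frames: np.ndarray  # (n_frames, frame_length)
    frame_length: int
    hop: int
    voiced_span: tuple  # [start, end) sample indices into the input trace

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2:
            raise ValueError("frames must be a 2-D matrix")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")


def pre_emphasis(x, alpha: float = 0.98) -> np.ndarray:
    """First-order high-pass: y[0] = x[0]; y[n] = x[n] - alpha * x[n-1]."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 1:
        raise ValueError("trace must have at least one sample")
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return y


def _frame_stats(x: np.ndarray, config: PreprocessConfig):
    """Short-time RMS and zero-crossing rate on the analysis grid."""
    flen, hop = config.analysis_frame, config.analysis_hop
    if x.size < flen:
        pad = np.zeros(flen - x.size)
        x = np.concatenate([x, pad])
    n = 1 + (x.size - flen) // hop
    idx = np.arange(flen)[None, :] + hop * np.arange(n)[:, None]
    frames = x[idx]
    rms = np.sqrt(np.mean(frames**2, axis=1))
    signs = np.signbit(frames)
    zcr = np.mean(signs[:, 1:] != signs[:, :-1], axis=1)
    return rms, zcr


def _voiced_mask(x: np.ndarray, config: PreprocessConfig):
    """Per-analysis-frame speech mask via double-threshold hysteresis."""
    rms, zcr = _frame_stats(x, config)
    n_cal = max(1, int(config.calibration_ms / config.analysis_hop_ms))
    noise = max(float(np.median(rms[:n_cal])), 1e-6)
    peak = float(rms.max()) if rms.size else 0.0
    t_high = max(config.energy_high_factor * noise, config.energy_floor_frac * peak)
    t_low = max(config.energy_low_factor * noise, 0.5 * config.energy_floor_frac * peak)
    # a loud calibration prefix means speech starts immediately; fall back
    # to a peak-relative threshold, but only above an absolute speech level
    # (signals are normalized to [-1, 1]) so pure noise still reads silent
    if t_high > 0.5 * peak and peak >= config.min_speech_rms:
        t_high = 0.5 * peak
        t_low = min(t_low, 0.25 * peak)
    speechlike = zcr < config.zcr_threshold
    seed = (rms > t_high) & speechlike
    mask = seed.copy()
    # hysteresis: grow seeds into neighbours above the low threshold
    above_low = (rms > t_low) & speechlike
    changed = True
    while changed:
        left = np.concatenate([[False], mask[:-1]])
        right = np.concatenate([mask[1:], [False]])
        grown = mask | (above_low & (left | right))
        changed = bool(np.any(grown & ~mask))
        mask = grown
    return mask, rms


def _mask_to_regions(mask: np.ndarray, config: PreprocessConfig):
    """Contiguous True runs of the mask as sample-index [start, end) pairs."""
    hop, flen = config.analysis_hop, config.analysis_frame
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    min_frames = max(1, int(config.min_voiced_ms / config.analysis_hop_ms))
    regions = []
    for s, e in zip(starts, ends):
        if e - s >= min_frames:
            regions.append((int(s * hop), int((e - 1) * hop + flen)))
    return regions


def voiced_regions(x, config: PreprocessConfig = PreprocessConfig()):
    """All detected speech segments as [start, end) sample-index pairs."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < config.analysis_frame:
        raise ValueError("trace shorter than one analysis frame")
    mask, _ = _voiced_mask(x, config)
    return [(s, min(e, x.size)) for s, e in _mask_to_regions(mask, config)]


def detect_endpoints(x, config: PreprocessConfig = PreprocessConfig()):
    """Tightest [start, end) span containing every detected speech segment.

    Returns ``(0, 0)`` (an empty span) when nothing passes the detector.
    """
    regions = voiced_regions(x, config)
    if not regions:
        return (0, 0)
    return (regions[0][0], regions[-1][1])


def frame_and_window(x, span, config: PreprocessConfig = PreprocessConfig()) -> FrameSequence:
    """Cut the span into exactly ``n_frames`` overlapping Hamming frames.

    hop = max(1, floor((span_len - frame_length) / (n_frames - 1))); the
    span is zero-padded on the right when shorter than the maximally
    overlapped layout (frame_length + n_frames - 1 samples).
    """
    x = np.asarray(x, dtype=np.float64)
    start, end = int(span[0]), int(span[1])
    flen, nf = config.frame_length, config.n_frames
    span_len = end - start
    if span_len < flen:
        raise ValueError(
            f"span length {span_len} shorter than frame length {flen}; "
            f"need at least {flen} samples"
        )
    seg = x[start:end]
    hop = max(1, (span_len - flen) // (nf - 1))
    needed = (nf - 1) * hop + flen
    if needed > seg.size:
        seg = np.concatenate([seg, np.zeros(needed - seg.size)])
    idx = np.arange(flen)[None, :] + hop * np.arange(nf)[:, None]
    frames = seg[idx] * hamming(flen, sym=False)
    return FrameSequence(frames=frames, frame_length=flen, hop=hop, voiced_span=(start, end))


def preprocess_recording(x, config: PreprocessConfig = PreprocessConfig()) -> FrameSequence:
    """Full conditioning chain: pre-emphasis → endpoints → frame + window."""
    y = pre_emphasis(x, config.preemphasis_alpha)
    span = detect_endpoints(y, config)
    if span[1] - span[0] < config.frame_length:
        raise ValueError("no usable speech detected in recording")
    return frame_and_window(y, span, config)
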