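"""Emulation of the wireless patch data path.

Models the analog front end (voltage divider off a 3.3 V supply), the
12-bit / 4 ksps analog-to-digital conversion, and the IMA ADPCM codec
used to compress samples before transmission. Downstream stages consume
exactly what this chain delivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TelemetryConfig",
    "CompressedStream",
    "resistance_to_voltage",
    "voltage_to_resistance",
    "adc_quantize",
    "adc_to_normalized",
    "normalized_to_voltage",
    "adpcm_encode",
    "adpcm_decode",
    "adpcm_roundtrip",
]

ADC_BITS = 12
ADC_FULL_SCALE = (1 << ADC_BITS) - 1  # 4095
ADC_MIDPOINT = 1 << (ADC_BITS - 1)  # 2048


@dataclass(frozen=True)
class TelemetryConfig:
    supply_voltage: float = 3.3
    reference_resistance: float = 10_000.0
    adc_bits: int = ADC_BITS
    sampling_rate: int = 4000
    adpcm_bits_per_sample: int = 4

    def __post_init__(self) -> None:
        if self.supply_voltage <= 0:
            raise ValueError(f"supply_voltage must be positive, got {self.supply_voltage}")
        if self.reference_resistance <= 0:
            raise ValueError(
                f"reference_resistance must be positive, got {self.reference_resistance}"
            )
        if self.adpcm_bits_per_sample != 4:
            raise ValueError("only the 4-bit IMA ADPCM codec is implemented")


@dataclass
class CompressedStream:
    """Packed 4-bit ADPCM codes plus the initial predictor state."""

    codes: np.ndarray  # uint8, one nibble per entry (unpacked for clarity)
    initial_predictor: int
    initial_step_index: int
    n_samples: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.size != self.n_samples:
            raise ValueError(
                f"codes length {self.codes.size} inconsistent with n_samples {self.n_samples}"
            )

    def to_bytes(self) -> bytes:
        """Serialize as raw blob: 8-byte header then packed nibbles."""
        header = (
            int(self.n_samples).to_bytes(4, "little")
            + int(self.initial_predictor % (1 << 16)).to_bytes(2, "little")
            + int(self.initial_step_index).to_bytes(2, "little")
        )
        codes = self.codes
        if codes.size % 2:
            codes = np.concatenate([codes, np.zeros(1, dtype=np.uint8)])
        packed = (codes[0::2] | (codes[1::2] << 4)).astype(np.uint8)
        return header + packed.tobytes()

    @classmethod
    def from_bytes(cls, blob: bytes) -> "CompressedStream":
        n = int.from_bytes(blob[0:4], "little")
        pred = int.from_bytes(blob[4:6], "little")
        if pred >= 1 << 15:
            pred -= 1 << 16
        step = int.from_bytes(blob[6:8], "little")
        packed = np.frombuffer(blob[8:], dtype=np.uint8)
        codes = np.empty(packed.size * 2, dtype=np.uint8)
        codes[0::2] = packed & 0x0F
        codes[1::2] = packed >> 4
        return cls(codes=codes[:n], initial_predictor=pred, initial_step_index=step, n_samples=n)


def resistance_to_voltage(r_sensor, config: TelemetryConfig = TelemetryConfig()):
    """Voltage-divider readout: v = Vcc * R / (R + Rref).

    Accepts a scalar or an array of sensor resistances in ohms.
    """
    r = np.asarray(r_sensor, dtype=np.float64)
    if np.any(r < 0):
        bad = float(np.min(r))
        raise ValueError(f"sensor resistance must be nonnegative, got {bad}")
    v = config.supply_voltage * r / (r + config.reference_resistance)
    return float(v) if np.isscalar(r_sensor) else v


def voltage_to_resistance(v, config: TelemetryConfig = TelemetryConfig()):
    """Inverse divider: the sensor resistance that yields voltage ``v``.

    Used by the signal generator, which synthesizes in the voltage domain.
    """
    v = np.asarray(v, dtype=np.float64)
    if np.any(v < 0) or np.any(v >= config.supply_voltage):
        raise ValueError("voltage must lie in [0, supply_voltage)")
    r = config.reference_resistance * v / (config.supply_voltage - v)
    return r


def adc_quantize(v, config: TelemetryConfig = TelemetryConfig()) -> np.ndarray:
    """Quantize a voltage trace to 12-bit codes.

    codes = floor(clip(v, 0, Vcc) / Vcc * 4095 + 0.5), each in [0, 4095].
    Out-of-range voltages clip; that is the contract, not an error.
    """
    v = np.atleast_1d(np.asarray(v, dtype=np.float64))
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage trace must be finite")
    full = (1 << config.adc_bits) - 1
    clipped = np.clip(v, 0.0, config.supply_voltage)
    codes = np.floor(clipped / config.supply_voltage * full + 0.5).astype(np.int32)
    return codes


def adc_to_normalized(codes) -> np.ndarray:
    """Map 12-bit codes to [-1, 1] about the ADC midpoint."""
    return (np.asarray(codes, dtype=np.float64) - ADC_MIDPOINT) / ADC_MIDPOINT


def normalized_to_voltage(x, config: TelemetryConfig = TelemetryConfig()) -> np.ndarray:
    """Map a normalized [-1, 1] trace onto the ADC input range about mid-supply."""
    half = config.supply_voltage / 2.0
    return half + np.asarray(x, dtype=np.float64) * half


# IMA ADPCM tables (standard).
_STEP_TABLE = np.array(
    [
        7, 8, 9, 10, 11, 12, 13, 14, 16, 17, 19, 21, 23, 25, 28, 31, 34, 37,
        41, 45, 50, 55, 60, 66, 73, 80, 88, 97, 107, 118, 130, 143, 157, 173,
        190, 209, 230, 253, 279, 307, 337, 371, 408, 449, 494, 544, 598, 658,
        724, 796, 876, 963, 1060, 1166, 1282, 1411, 1552, 1707, 1878, 2066,
        2272, 2499, 2749, 3024, 3327, 3660, 4026, 4428, 4871, 5358, 5894,
        6484, 7132, 7845, 8630, 9493, 10442, 11487, 12635, 13899, 15289,
        16818, 18500, 20350, 22385, 24623, 27086, 29794, 32767,
    ],
    dtype=np.int32,
)

_INDEX_TABLE = np.array([-1, -1, -1, -1, 2, 4, 6, 8], dtype=np.int32)

_PRED_MIN, _PRED_MAX = -(1 << 15), (1 << 15) - 1


def _center(samples: np.ndarray) -> np.ndarray:
    return samples.astype(np.int32) - ADC_MIDPOINT


def _initial_step_index(centered: np.ndarray) -> int:
    """Seed the step size near the first sample difference (faster attack)."""
    if centered.size < 2:
        return 0
    return int(np.clip(np.searchsorted(_STEP_TABLE, abs(int(centered[1]) - int(centered[0]))), 0, 88))


def adpcm_encode(samples) -> CompressedStream:
    """Encode 12-bit ADC codes with 4-bit IMA ADPCM.

    The predictor operates on sign-centered values (code - 2048). The first
    sample seeds the predictor, so decoding reproduces it exactly.
    """
    samples = np.asarray(samples, dtype=np.int64)
    if samples.size and (samples.min() < 0 or samples.max() > ADC_FULL_SCALE):
        raise ValueError("samples must be 12-bit ADC codes in [0, 4095]")
    n = samples.size
    if n == 0:
        return CompressedStream(
            codes=np.empty(0, dtype=np.uint8), initial_predictor=0,
            initial_step_index=0, n_samples=0,
        )
    centered = _center(samples)
    predictor = int(centered[0])
    step_index = _initial_step_index(centered)
    codes = np.empty(n, dtype=np.uint8)
    step_table = _STEP_TABLE
    index_table = _INDEX_TABLE
    init_pred, init_step = predictor, step_index
    for i in range(n):
        step = int(step_table[step_index])
        diff = int(centered[i]) - predictor
        code = 0
        if diff < 0:
            code = 8
            diff = -diff
        delta = step >> 3
        if diff >= step:
            code |= 4
            diff -= step
            delta += step
        if diff >= step >> 1:
            code |= 2
            diff -= step >> 1
            delta += step >> 1
        if diff >= step >> 2:
            code |= 1
            delta += step >> 2
        predictor += -delta if code & 8 else delta
        predictor = min(max(predictor, _PRED_MIN), _PRED_MAX)
        step_index = min(max(step_index + int(index_table[code & 7]), 0), 88)
        codes[i] = code
    return CompressedStream(
        codes=codes, initial_predictor=init_pred,
        initial_step_index=init_step, n_samples=n,
    )


def adpcm_decode(stream: CompressedStream) -> np.ndarray:
    """Decode a compressed stream back to 12-bit ADC codes."""
    n = stream.n_samples
    out = np.empty(n, dtype=np.int32)
    predictor = int(stream.initial_predictor)
    step_index = int(stream.initial_step_index)
    step_table = _STEP_TABLE
    index_table = _INDEX_TABLE
    codes = stream.codes
    for i in range(n):
        code = int(codes[i])
        step = int(step_table[step_index])
        delta = step >> 3
        if code & 4:
            delta += step
        if code & 2:
            delta += step >> 1
        if code & 1:
            delta += step >> 2
        predictor += -delta if code & 8 else delta
        predictor = min(max(predictor, _PRED_MIN), _PRED_MAX)
        step_index = min(max(step_index + int(index_table[code & 7]), 0), 88)
        out[i] = predictor
    return np.clip(out + ADC_MIDPOINT, 0, ADC_FULL_SCALE)


def adpcm_roundtrip(samples) -> np.ndarray:
    """Encode then decode; returns a trace of identical length."""
    return adpcm_decode(adpcm_encode(samples))


try:  # numba acceleration for the sequential codec loops, if available
    from numba import njit as _njit

    _enc_loop_src = adpcm_encode
    _dec_loop_src = adpcm_decode

    @_njit(cache=True)
    def _encode_loop(centered, step_index, step_table, index_table):  # pragma: no cover
        n = centered.shape[0]
        codes = np.empty(n, dtype=np.uint8)
        predictor = int(centered[0])
        for i in range(n):
            step = step_table[step_index]
            diff = centered[i] - predictor
            code = 0
            if diff < 0:
                code = 8
                diff = -diff
            delta = step >> 3
            if diff >= step:
                code |= 4
                diff -= step
                delta += step
            if diff >= step >> 1:
                code |= 2
                diff -= step >> 1
                delta += step >> 1
            if diff >= step >> 2:
                code |= 1
                delta += step >> 2
            if code & 8:
                predictor -= delta
            else:
                predictor += delta
            if predictor < _PRED_MIN:
                predictor = _PRED_MIN
            elif predictor > _PRED_MAX:
                predictor = _PRED_MAX
            step_index += index_table[code & 7]
            if step_index < 0:
                step_index = 0
            elif step_index > 88:
                step_index = 88
            codes[i] = code
        return codes

    @_njit(cache=True)
    def _decode_loop(codes, predictor, step_index, step_table, index_table):  # pragma: no cover
        n = codes.shape[0]
        out = np.empty(n, dtype=np.int32)
        for i in range(n):
            code = codes[i]
            step = step_table[step_index]
            delta = step >> 3
            if code & 4:
                delta += step
            if code & 2:
                delta += step >> 1
            if code & 1:
                delta += step >> 2
            if code & 8:
                predictor -= delta
            else:
                predictor += delta
            if predictor < _PRED_MIN:
                predictor = _PRED_MIN
            elif predictor > _PRED_MAX:
                predictor = _PRED_MAX
            step_index += index_table[code & 7]
            if step_index < 0:
                step_index = 0
            elif step_index > 88:
                step_index = 88
            out[i] = predictor
        return out

    def adpcm_encode(samples) -> CompressedStream:  # noqa: F811
        samples = np.asarray(samples, dtype=np.int64)
        if samples.size and (samples.min() < 0 or samples.max() > ADC_FULL_SCALE):
            raise ValueError("samples must be 12-bit ADC codes in [0, 4095]")
        if samples.size == 0:
            return CompressedStream(
                codes=np.empty(0, dtype=np.uint8), initial_predictor=0,
                initial_step_index=0, n_samples=0,
            )
        centered = _center(samples)
        init_step = _initial_step_index(centered)
        codes = _encode_loop(centered.astype(np.int64), init_step,
                             _STEP_TABLE.astype(np.int64),
                             _INDEX_TABLE.astype(np.int64))
        return CompressedStream(
            codes=codes, initial_predictor=int(centered[0]),
            initial_step_index=init_step, n_samples=samples.size,
        )

    def adpcm_decode(stream: CompressedStream) -> np.ndarray:  # noqa: F811
        if stream.n_samples == 0:
            return np.empty(0, dtype=np.int32)
        out = _decode_loop(
            stream.codes.astype(np.int64), int(stream.initial_predictor),
            int(stream.initial_step_index), _STEP_TABLE.astype(np.int64),
            _INDEX_TABLE.astype(np.int64),
        )
        return np.clip(out.astype(np.int32) + ADC_MIDPOINT, 0, ADC_FULL_SCALE)

    adpcm_encode.__doc__ = _enc_loop_src.__doc__
    adpcm_decode.__doc__ = _dec_loop_src.__doc__
except Exception:  # pragma: no cover - numba optional
    pass
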