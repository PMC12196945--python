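"""Binary sensor-frame stream codec for the accelerometer array.

The acquisition front end polls eight triaxial accelerometers in a fixed
round-robin (A..H) and emits, per sensor read, a 48-bit payload of three
signed 16-bit axis counts (x, y, z).  The serial link itself carries no
published framing, so this module defines a self-consistent on-wire dialect
and ships both encoder and decoder:

    [0xAA 0x55] [sensor index: 1 byte] [x y z: 3 x int16 little-endian]

9 bytes per frame.  The decoder resynchronizes on the 2-byte sync pattern
after corruption, counting and reporting dropped bytes.  Raw counts convert
to acceleration via a linear scale, default 3.9 mg/LSB (the named
accelerometer's full-resolution sensitivity).
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SensorFrame",
    "StreamConfig",
    "FrameError",
    "encode_frame",
    "parse_frame",
    "parse_stream",
    "encode_stream",
    "demux_stream",
    "mux_frames",
    "counts_to_g",
    "per_channel_rate",
]

SYNC = b"\xaa\x55"
_PAYLOAD = struct.Struct("<hhh")
FRAME_SIZE = len(SYNC) + 1 + _PAYLOAD.size  # 9 bytes


class FrameError(ValueError):
    """Malformed or truncated frame."""


@dataclass(frozen=True)
class SensorFrame:
    """One sensor read: index 0-7 and three signed 16-bit axis counts."""

    sensor_index: int
    x_raw: int
    y_raw: int
    z_raw: int

    def __post_init__(self) -> None:
        if not 0 <= self.sensor_index <= 7:
            raise FrameError(f"sensor index {self.sensor_index} outside 0-7")
        for v in (self.x_raw, self.y_raw, self.z_raw):
            if not -32768 <= v <= 32767:
                raise FrameError(f"axis count {v} outside int16 range")


@dataclass(frozen=True)
class StreamConfig:
    """Stream dialect parameters; scale is g per count."""

    sensor_count: int = 8
    scale: float = 3.9e-3

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.sensor_count < 1:
            raise ValueError("sensor_count must be positive")


def encode_frame(frame: SensorFrame, config: StreamConfig = StreamConfig()) -> bytes:
    return (
        SYNC
        + bytes([frame.sensor_index])
        + _PAYLOAD.pack(frame.x_raw, frame.y_raw, frame.z_raw)
    )


def parse_frame(data: bytes, config: StreamConfig = StreamConfig()) -> SensorFrame:
    """Decode a single frame starting at offset 0."""
    if len(data) < FRAME_SIZE:
        raise FrameError(
            f"truncated frame: need {FRAME_SIZE} bytes, got {len(data)}"
        )
    if data[:2] != SYNC:
        raise FrameError("bad sync bytes at frame start")
    sensor = data[2]
    if sensor >= config.sensor_count:
        raise FrameError(f"sensor index {sensor} >= {config.sensor_count}")
    x, y, z = _PAYLOAD.unpack_from(data, 3)
    return SensorFrame(sensor_index=sensor, x_raw=x, y_raw=y, z_raw=z)


def parse_stream(
    data: bytes, config: StreamConfig = StreamConfig()
) -> tuple[list[SensorFrame], int]:
    """Decode every frame in a byte stream, resynchronizing on corruption.

    Returns (frames, dropped_bytes).  Bytes skipped while hunting for the
    sync pattern are counted and reported with a warning.
    """
    frames: list[SensorFrame] = []
    dropped = 0
    pos = 0
    n = len(data)
    while pos + FRAME_SIZE <= n:
        try:
            frames.append(parse_frame(data[pos : pos + FRAME_SIZE], config))
            pos += FRAME_SIZE
        except FrameError:
            pos += 1
            dropped += 1
    dropped += n - pos  # trailing partial frame, if any
    if dropped:
        warnings.warn(
            f"dropped {dropped} unparseable byte(s) during stream decode",
            stacklevel=2,
        )
    return frames, dropped


def mux_frames(counts: np.ndarray, config: StreamConfig = StreamConfig()) -> list[SensorFrame]:
    """Round-robin frame sequence from a (N, sensors, 3) count array."""
    counts = np.asarray(counts)
    if counts.ndim != 3 or counts.shape[1] != config.sensor_count or counts.shape[2] != 3:
        raise ValueError(
            f"expected (N, {config.sensor_count}, 3) counts, got {counts.shape}"
        )
    return [
        SensorFrame(s, int(counts[t, s, 0]), int(counts[t, s, 1]), int(counts[t, s, 2]))
        for t in range(counts.shape[0])
        for s in range(config.sensor_count)
    ]


def encode_stream(counts: np.ndarray, config: StreamConfig = StreamConfig()) -> bytes:
    return b"".join(encode_frame(f, config) for f in mux_frames(counts, config))


def demux_stream(
    frames: list[SensorFrame] | bytes, config: StreamConfig = StreamConfig()
) -> np.ndarray:
    """Time-align round-robin frames into a (N, sensors, 3) count array.

    A frame arriving out of round-robin order aborts the current polling
    cycle and resynchronizes at the next sensor-0 frame; incomplete cycles
    (including a trailing one) are discarded with a warning.
    """
    if isinstance(frames, (bytes, bytearray)):
        frames, _ = parse_stream(bytes(frames), config)
    S = config.sensor_count
    cycles: list[list[SensorFrame]] = []
    current: list[SensorFrame] = []
    discarded = 0
    for fr in frames:
        if fr.sensor_index != len(current):
            discarded += len(current) + (0 if fr.sensor_index == 0 else 1)
            current = [fr] if fr.sensor_index == 0 else []
            if len(current) == S:  # S == 1 corner case
                cycles.append(current)
                current = []
            continue
        current.append(fr)
        if len(current) == S:
            cycles.append(current)
            current = []
    discarded += len(current)
    if discarded:
        warnings.warn(
            f"discarded {discarded} frame(s) from incomplete or out-of-order "
            "polling cycles",
            stacklevel=2,
        )
    out = np.empty((len(cycles), S, 3), dtype=np.int32)
    for t, cyc in enumerate(cycles):
        for s, fr in enumerate(cyc):
            out[t, s] = (fr.x_raw, fr.y_raw, fr.z_raw)
    return out


def counts_to_g(raw: np.ndarray | int, config: StreamConfig = StreamConfig()) -> np.ndarray | float:
    """Linear count-to-acceleration conversion (g); sign-preserving."""
    return np.asarray(raw, dtype=float) * config.scale


def per_channel_rate(aggregate_rate_hz: float, config: StreamConfig = StreamConfig()) -> float:
    """Effective per-sensor rate of a round-robin poll at the aggregate rate."""
    return aggregate_rate_hz / config.sensor_count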