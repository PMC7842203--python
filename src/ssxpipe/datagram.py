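"""Bit-exact datagram packetization, a lossy channel, and order-independent
frame assembly — a software emulation of one-sided RDMA WRITE semantics.

Each datagram carries its own destination byte offset, so the assembler
can place payloads in the frame buffer in any arrival order with no
reshuffle step.  The final datagram of a frame (largest packet index) is
flagged and carries a 32-bit "immediate" completion value, emulating
WRITE_WITH_IMM: the assembler surfaces that event only once the frame is
byte-complete.

Wire format (all integers little-endian):

    offset  size  field
    0       4     magic "JFDG"
    4       2     version (uint16, currently 1)
    6       8     frame_id (uint64)
    14      4     packet_seq (uint32, globally incrementing)
    18      4     packets_in_frame (uint32)
    22      4     packet_index (uint32)
    26      8     dest_offset (uint64, byte offset in the frame buffer)
    34      4     row_start (uint32, first detector row covered)
    38      2     payload_len (uint16)
    40      2     flags (uint16; bit 0 = last packet, immediate valid)
    42      4     immediate (uint32 completion event value)
    46      8     timestamp (uint64, arbitrary ticks)
    54      8192  payload slot (four lines of 1024 16-bit pixels when full)

54 + 8192 = 8246 bytes per serialized datagram.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .errors import (
    BadMagicError,
    IntegrityError,
    TruncatedError,
    UnsupportedVersionError,
    ValidationError,
)
from .synthetic import RawFrame

MAGIC = b"JFDG"
VERSION = 1
HEADER = struct.Struct("<4sHQIIIQIHHIQ")
HEADER_SIZE = HEADER.size  # 54
PAYLOAD_SLOT = 8192
DATAGRAM_SIZE = HEADER_SIZE + PAYLOAD_SLOT  # 8246
PIXELS_PER_PACKET = PAYLOAD_SLOT // 2  # 4096 = four lines of 1024
FLAG_LAST = 0x0001

assert HEADER_SIZE == 54


@dataclass(frozen=True)
class Datagram:
    frame_id: int
    packet_seq: int
    packets_in_frame: int
    packet_index: int
    dest_offset: int
    row_start: int
    payload: bytes
    flags: int = 0
    immediate: int = 0
    timestamp: int = 0
    version: int = VERSION

    @property
    def payload_len(self) -> int:
        return len(self.payload)

    @property
    def is_last(self) -> bool:
        return bool(self.flags & FLAG_LAST)


def serialize(d: Datagram) -> bytes:
    """Serialize to the fixed 8246-byte wire form (payload slot padded)."""
    if d.payload_len > PAYLOAD_SLOT:
        raise ValidationError(
            f"payload of {d.payload_len} bytes exceeds the {PAYLOAD_SLOT}-byte slot"
        )
    header = HEADER.pack(
        MAGIC,
        d.version,
        d.frame_id,
        d.packet_seq,
        d.packets_in_frame,
        d.packet_index,
        d.dest_offset,
        d.row_start,
        d.payload_len,
        d.flags,
        d.immediate,
        d.timestamp,
    )
    return header + d.payload + b"\x00" * (PAYLOAD_SLOT - d.payload_len)


def parse(buf: bytes) -> Datagram:
    """Parse one serialized datagram; inverse of :func:`serialize`."""
    if len(buf) < HEADER_SIZE:
        raise TruncatedError(
            f"buffer of {len(buf)} bytes is shorter than the {HEADER_SIZE}-byte header"
        )
    (
        magic,
        version,
        frame_id,
        packet_seq,
        packets_in_frame,
        packet_index,
        dest_offset,
        row_start,
        payload_len,
        flags,
        immediate,
        timestamp,
    ) = HEADER.unpack_from(buf)
    if magic != MAGIC:
        raise BadMagicError(f"bad magic {magic!r}, expected {MAGIC!r}")
    if version != VERSION:
        raise UnsupportedVersionError(f"unsupported datagram version {version}")
    if len(buf) < HEADER_SIZE + payload_len:
        raise TruncatedError(
            f"payload truncated: header promises {payload_len} bytes, "
            f"buffer holds {len(buf) - HEADER_SIZE}"
        )
    payload = bytes(buf[HEADER_SIZE : HEADER_SIZE + payload_len])
    return Datagram(
        frame_id=frame_id,
        packet_seq=packet_seq,
        packets_in_frame=packets_in_frame,
        packet_index=packet_index,
        dest_offset=dest_offset,
        row_start=row_start,
        payload=payload,
        flags=flags,
        immediate=immediate,
        timestamp=timestamp,
        version=version,
    )


def packetize(raw: RawFrame, frame_id: int, seq_start: int = 0) -> list[Datagram]:
    """Split a raw frame into destination-addressed datagrams.

    Payloads cover the frame contiguously in row-major byte order,
    ``PAYLOAD_SLOT`` bytes per datagram (the last one may be short when the
    frame size is not a multiple of 4096 pixels).  ``packet_seq`` counts up
    from ``seq_start``; the last datagram carries the completion flag and
    ``immediate = frame_id mod 2**32``.
    """
    rows, cols = raw.shape
    if rows * cols == 0:
        raise ValidationError("cannot packetize an empty frame")
    blob = np.ascontiguousarray(raw.words, dtype="<u2").tobytes()
    n_packets = (len(blob) + PAYLOAD_SLOT - 1) // PAYLOAD_SLOT
    out = []
    for i in range(n_packets):
        off = i * PAYLOAD_SLOT
        payload = blob[off : off + PAYLOAD_SLOT]
        last = i == n_packets - 1
        out.append(
            Datagram(
                frame_id=frame_id,
                packet_seq=seq_start + i,
                packets_in_frame=n_packets,
                packet_index=i,
                dest_offset=off,
                row_start=(off // 2) // cols,
                payload=payload,
                flags=FLAG_LAST if last else 0,
                immediate=(frame_id % 2**32) if last else 0,
                timestamp=seq_start + i,
            )
        )
    return out


# --- channel model --------------------------------------------------------


@dataclass(frozen=True)
class ChannelModel:
    """Seeded lossy / reordering channel; never duplicates or corrupts.

    Each datagram is dropped independently with ``loss_probability``; the
    survivors are permuted by a bounded-window shuffle in which no packet
    moves more than ``reorder_window`` positions from its original rank.
    """

    loss_probability: float = 0.0
    reorder_window: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.loss_probability <= 1:
            raise ValidationError("loss_probability must lie in [0, 1]")
        if self.reorder_window < 0:
            raise ValidationError("reorder_window must be >= 0")


def channel_transmit(datagrams: list[Datagram], model: ChannelModel) -> list[Datagram]:
    """Pass datagrams through the channel model.

    The loss decisions are the first ``len(datagrams)`` uniform draws of
    ``default_rng(model.seed)`` (packet i is dropped iff draw < p), which
    makes the dropped set exactly replayable from the seed alone.
    """
    rng = np.random.default_rng(model.seed)
    n = len(datagrams)
    u = rng.random(n)
    kept = [d for d, ui in zip(datagrams, u) if ui >= model.loss_probability]
    if model.reorder_window > 0 and len(kept) > 1:
        keys = np.arange(len(kept)) + rng.random(len(kept)) * model.reorder_window
        order = np.argsort(keys, kind="stable")
        kept = [kept[i] for i in order]
    return kept


def replay_dropped_set(n_packets: int, model: ChannelModel) -> set[int]:
    """Independently recompute which packet ranks the channel dropped."""
    u = np.random.default_rng(model.seed).random(n_packets)
    return set(np.flatnonzero(u < model.loss_probability).tolist())


# --- assembly -------------------------------------------------------------


@dataclass
class FrameResult:
    """Outcome of assembling one frame's datagrams."""

    frame_id: int
    shape: tuple[int, int]
    buffer: bytearray
    received_map: np.ndarray  # bool per packet index
    event: int | None = None  # immediate value, present only when complete

    @property
    def missing(self) -> list[int]:
        return np.flatnonzero(~self.received_map).tolist()

    @property
    def complete(self) -> bool:
        return bool(self.received_map.all())

    @property
    def frame(self) -> RawFrame:
        """Reassembled raw frame (missing regions are zero-filled)."""
        rows, cols = self.shape
        words = np.frombuffer(bytes(self.buffer), dtype="<u2").reshape(rows, cols)
        return RawFrame(words=words.astype(np.uint16))

    def missing_pixel_mask(self) -> np.ndarray:
        """Boolean mask of pixels covered by missing packets."""
        rows, cols = self.shape
        mask = np.zeros(rows * cols, dtype=bool)
        for idx in self.missing:
            lo = idx * PIXELS_PER_PACKET
            mask[lo : lo + PIXELS_PER_PACKET] = True
        return mask.reshape(rows, cols)


class FrameAssembler:
    """Incremental order-independent assembler for a single frame.

    Payloads are written straight at their destination offsets; identical
    duplicates are accepted idempotently (a WRITE rewrite is harmless),
    conflicting duplicates raise :class:`IntegrityError`.
    """

    def __init__(self, shape: tuple[int, int], frame_id: int | None = None):
        rows, cols = int(shape[0]), int(shape[1])
        if rows <= 0 or cols <= 0:
            raise ValidationError(f"invalid frame geometry {(rows, cols)}")
        self.shape = (rows, cols)
        self.frame_id = frame_id
        nbytes = rows * cols * 2
        self._nbytes = nbytes
        self._n_packets = (nbytes + PAYLOAD_SLOT - 1) // PAYLOAD_SLOT
        self._buffer = bytearray(nbytes)
        self._received = np.zeros(self._n_packets, dtype=bool)
        self._event: int | None = None

    def add(self, d: Datagram) -> None:
        if self.frame_id is None:
            self.frame_id = d.frame_id
        elif d.frame_id != self.frame_id:
            raise ValidationError(
                f"mixed frame_ids in assembly: {d.frame_id} != {self.frame_id}"
            )
        if not 0 <= d.packet_index < self._n_packets:
            raise ValidationError(
                f"packet_index {d.packet_index} outside 0..{self._n_packets - 1}"
            )
        end = d.dest_offset + d.payload_len
        if end > self._nbytes:
            raise ValidationError(
                f"payload [{d.dest_offset}, {end}) overruns the "
                f"{self._nbytes}-byte frame buffer"
            )
        if self._received[d.packet_index]:
            if bytes(self._buffer[d.dest_offset : end]) != d.payload:
                raise IntegrityError(
                    f"conflicting duplicate for packet {d.packet_index} "
                    f"of frame {self.frame_id}"
                )
        else:
            self._buffer[d.dest_offset : end] = d.payload
            self._received[d.packet_index] = True
        if d.is_last:
            self._event = d.immediate

    @property
    def complete(self) -> bool:
        return bool(self._received.all())

    def result(self) -> FrameResult:
        return FrameResult(
            frame_id=self.frame_id if self.frame_id is not None else -1,
            shape=self.shape,
            buffer=self._buffer,
            received_map=self._received.copy(),
            event=self._event if self.complete else None,
        )


def assemble(
    datagrams: list[Datagram], expected_frame_geometry: tuple[int, int]
) -> FrameResult:
    """Assemble one frame from its datagrams, in any order.

    The result is a pure function of the datagram *set*: every permutation
    of the input yields byte-identical output.  The completion event is
    reported only when no packet is missing.
    """
    asm = FrameAssembler(expected_frame_geometry)
    for d in datagrams:
        asm.add(d)
    return asm.result()


class SequenceGapMonitor:
    """Detects dropped packets from gaps in the global packet_seq stream."""

    def __init__(self, expected_start: int | None = None):
        self.expected_start = expected_start
        self._seen: set[int] = set()

    def observe(self, seq: int) -> None:
        self._seen.add(int(seq))

    @property
    def received(self) -> int:
        return len(self._seen)

    def missing_count(self, expected_end: int | None = None) -> int:
        """Number of sequence numbers absent from the observed span.

        With ``expected_start`` / ``expected_end`` the span is known
        exactly; otherwise only interior gaps (between the smallest and
        largest observed seq) are countable.
        """
        if not self._seen:
            if self.expected_start is not None and expected_end is not None:
                return expected_end - self.expected_start + 1
            return 0
        lo = self.expected_start if self.expected_start is not None else min(self._seen)
        hi = expected_end if expected_end is not None else max(self._seen)
        return (hi - lo + 1) - len(self._seen)


def frame_ids(datagrams: list[Datagram]) -> list[int]:
    """Distinct frame_ids in first-appearance order."""
    seen: dict[int, None] = {}
    for d in datagrams:
        seen.setdefault(d.frame_id, None)
    return list(seen)
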