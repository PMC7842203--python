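"""Credit-controlled, double-buffered three-stage processing loop.

The loop mirrors an online DAQ receiver: (1) ingest — datagrams are placed
order-independently into per-frame buffers and a completion event fires
when a frame is byte-complete; (2) compute — the frame is converted to
energies and either vetoed on its Bragg-pixel count or compressed to CSR
(darks instead update the running pedestal); (3) output — accepted results
are queued for transfer, with a credit bound on the number of in-flight
transfers.

Concurrency is emulated as a deterministic event-driven scheduler over
logical ticks: compute of frame n may overlap the ingest of later frames
(up to ``buffer_depth`` assembled-but-uncomputed frames in flight, 2 =
double buffering) and output transfers occupy a window of ticks so that
credit contention is observable in the event log.  The scheduler's
outputs and metrics are provably identical to a strictly sequential
reference (``run_sequential_reference``) — overlap is a throughput device,
never a semantic one.

Frame roles follow the chopper convention of the generator: even frame_id
= dark, odd = lit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np

from .calibration import GainTables, PedestalTracker, freeze_pedestal, update_pedestal
from .datagram import Datagram, FrameAssembler, FrameResult, SequenceGapMonitor
from .errors import ValidationError
from .reduction import (
    CSRImage,
    VetoConfig,
    correct_frame,
    csr_compress,
    default_csr_capacity,
    veto,
)
from .synthetic import EnergyFrame

logger = logging.getLogger("ssxpipe.pipeline")

#: logical ticks one output transfer occupies; longer than the compute
#: stage so that back-to-back accepted frames contend for credits
OUTPUT_TICKS = 3


@dataclass(frozen=True)
class PipelineConfig:
    """Orchestration and reduction parameters.

    ``mode``: "veto" emits the corrected EnergyFrame of accepted frames;
    "compress" emits CSR for every complete lit frame; "both" emits CSR
    for accepted frames only.  ``buffer_depth`` bounds assembled frames
    awaiting compute (2 = double buffering); ``credits`` bounds queued
    output transfers.  Incomplete frames are dropped by default, or
    processed with NaN in the missing payload zones.
    """

    buffer_depth: int = 2
    credits: int = 2
    mode: str = "veto"
    veto_cfg: VetoConfig = field(default_factory=VetoConfig)
    sparsify_threshold: float = 0.0
    csr_capacity: int | None = None
    incomplete_policy: str = "drop"  # or "nan"
    pedestal_mode: str = "running_mean"
    pedestal_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.buffer_depth < 1:
            raise ValidationError("buffer_depth must be >= 1")
        if self.credits < 1:
            raise ValidationError("credits must be >= 1")
        if self.mode not in ("veto", "compress", "both"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.incomplete_policy not in ("drop", "nan"):
            raise ValidationError(f"unknown incomplete policy {self.incomplete_policy!r}")


@dataclass(frozen=True)
class StageEvent:
    kind: str  # frame_complete | compute_start | compute_done | output_queued | output_done | credit_wait
    frame_id: int
    tick: int


@dataclass(frozen=True)
class FrameOutput:
    frame_id: int
    payload: Union[EnergyFrame, CSRImage]
    peak_count: int | None = None


@dataclass
class Metrics:
    frames_seen: int = 0
    darks_absorbed: int = 0
    lit_complete: int = 0
    accepted: int = 0
    rejected: int = 0
    incomplete: int = 0
    packets_received: int = 0
    packets_lost: int = 0
    bytes_in: int = 0
    bytes_out: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


@dataclass
class PipelineReport:
    outputs: list[FrameOutput]
    metrics: Metrics
    event_log: list[StageEvent]
    pedestal_count: int = 0


def stream_rate(
    frames_per_second: float, pixels_per_frame: float, bits_per_pixel: float
) -> float:
    """Raw data rate in gigabits per second (Gb/s, decimal: 1e9 bits)."""
    if frames_per_second < 0 or pixels_per_frame < 0 or bits_per_pixel < 0:
        raise ValidationError("rate arguments must be non-negative")
    return frames_per_second * pixels_per_frame * bits_per_pixel / 1e9


# --- ingest: shared by both runners --------------------------------------


def _ingest(
    datagrams: Iterable[Datagram], shape: tuple[int, int], metrics: Metrics
) -> list[FrameResult]:
    """Assemble the stream into frames, preserving completion order.

    Returns complete frames in the order their final packet arrived,
    followed by any frames left incomplete when the stream ended.
    """
    assemblers: dict[int, FrameAssembler] = {}
    completed: list[int] = []
    done: set[int] = set()
    monitor = SequenceGapMonitor()
    for d in datagrams:
        metrics.packets_received += 1
        metrics.bytes_in += d.payload_len
        monitor.observe(d.packet_seq)
        asm = assemblers.get(d.frame_id)
        if asm is None:
            asm = assemblers[d.frame_id] = FrameAssembler(shape, d.frame_id)
        asm.add(d)
        if asm.complete and d.frame_id not in done:
            done.add(d.frame_id)
            completed.append(d.frame_id)
    metrics.packets_lost = monitor.missing_count()
    results = [assemblers[fid].result() for fid in completed]
    for fid, asm in assemblers.items():
        if fid not in done:
            results.append(asm.result())
    return results


def _role(frame_id: int) -> str:
    return "dark" if frame_id % 2 == 0 else "lit"


def _output_bytes(payload: Union[EnergyFrame, CSRImage]) -> int:
    if isinstance(payload, EnergyFrame):
        return payload.values.size * 4
    return payload.indptr.nbytes + payload.indices.nbytes + payload.data.nbytes


def _compute_lit(
    fr: FrameResult,
    tables: GainTables,
    cfg: PipelineConfig,
) -> tuple[bool, FrameOutput | None]:
    """Correct + veto/compress one complete (or NaN-patched) lit frame."""
    energy = correct_frame(fr.frame, tables)
    if not fr.complete:  # incomplete_policy == "nan"
        vals = energy.values.copy()
        vals[fr.missing_pixel_mask()] = np.nan
        energy = EnergyFrame(values=vals)
    accept, count = veto(energy, cfg.veto_cfg)
    if cfg.mode == "compress":
        accept = True  # compression replaces rejection
    if not accept:
        return False, None
    if cfg.mode == "veto":
        payload: Union[EnergyFrame, CSRImage] = energy
    else:
        cap = cfg.csr_capacity
        if cap is None:
            cap = default_csr_capacity(energy.shape)
        payload = csr_compress(energy, cfg.sparsify_threshold, cap)
    return True, FrameOutput(frame_id=fr.frame_id, payload=payload, peak_count=count)


# --- the pipelined runner -------------------------------------------------


def run_pipeline(
    datagrams: Iterable[Datagram],
    tables: GainTables,
    cfg: PipelineConfig | None = None,
) -> PipelineReport:
    """Run the three-stage pipeline over a datagram stream.

    A frame's compute begins strictly after its completion event; at most
    ``buffer_depth`` frames sit assembled-but-uncomputed, and at most
    ``credits`` output transfers are in flight at any tick (the source
    blocks on ``credit_wait`` otherwise).  Darks update the pedestal
    tracker and produce no output; the updated pedestal applies to frames
    computed after the dark.  Outputs and metrics are identical to
    :func:`run_sequential_reference` for any ``buffer_depth`` / ``credits``.
    """
    cfg = cfg or PipelineConfig()
    metrics = Metrics()
    events: list[StageEvent] = []
    outputs: list[FrameOutput] = []
    shape = tables.shape
    tracker = PedestalTracker(shape=shape, mode=cfg.pedestal_mode, alpha=cfg.pedestal_alpha)
    current_tables = tables

    results = _ingest(datagrams, shape, metrics)
    metrics.frames_seen = len(results)

    prev_fc = 0
    compute_free = 0  # tick at which the compute unit becomes free
    compute_done_ticks: list[int] = []  # per processed frame, for buffer_depth
    in_flight: list[int] = []  # output_done ticks of queued transfers

    for fr in results:
        if not fr.complete and cfg.incomplete_policy == "drop":
            metrics.incomplete += 1
            continue
        if not fr.complete and _role(fr.frame_id) == "dark":
            # a partial dark must not poison the pedestal estimate
            metrics.incomplete += 1
            continue

        # ingest: completion gated by buffer availability (double buffering);
        # with free buffers it overlaps the compute of earlier frames
        fc = prev_fc + 1
        if len(compute_done_ticks) >= cfg.buffer_depth:
            fc = max(fc, compute_done_ticks[-cfg.buffer_depth])
        prev_fc = fc
        events.append(StageEvent("frame_complete", fr.frame_id, fc))
        if fr.complete:
            logger.debug("frame %d complete (event %s)", fr.frame_id, fr.event)

        # compute stage
        cs = max(fc + 1, compute_free)
        ce = cs + 1
        events.append(StageEvent("compute_start", fr.frame_id, cs))
        if _role(fr.frame_id) == "dark":
            update_pedestal(tracker, fr.frame)
            current_tables = freeze_pedestal(tracker, tables)
            metrics.darks_absorbed += 1
            accepted, out = False, None
        else:
            metrics.lit_complete += 1
            accepted, out = _compute_lit(fr, current_tables, cfg)
            if accepted:
                metrics.accepted += 1
            else:
                metrics.rejected += 1
        events.append(StageEvent("compute_done", fr.frame_id, ce))
        compute_free = ce
        compute_done_ticks.append(ce)

        # output stage, credit controlled
        if out is not None:
            oq = ce
            in_flight = [t for t in in_flight if t > oq]
            if len(in_flight) >= cfg.credits:
                events.append(StageEvent("credit_wait", fr.frame_id, oq))
                oq = sorted(in_flight)[len(in_flight) - cfg.credits]
                in_flight = [t for t in in_flight if t > oq]
            events.append(StageEvent("output_queued", fr.frame_id, oq))
            od = oq + OUTPUT_TICKS
            events.append(StageEvent("output_done", fr.frame_id, od))
            in_flight.append(od)
            outputs.append(out)
            metrics.bytes_out += _output_bytes(out.payload)

    return PipelineReport(
        outputs=outputs,
        metrics=metrics,
        event_log=events,
        pedestal_count=tracker.count,
    )


def run_sequential_reference(
    datagrams: Iterable[Datagram],
    tables: GainTables,
    cfg: PipelineConfig | None = None,
) -> PipelineReport:
    """Strictly sequential oracle: one frame at a time, buffer depth 1.

    Implements the identical contract as :func:`run_pipeline` as a plain
    loop with no scheduler: assemble, then per frame in completion order
    update pedestal (dark) or correct + veto/compress (lit), queuing at
    most one output at a time.  Used to prove the pipelined runner
    semantically equivalent.
    """
    cfg = cfg or PipelineConfig()
    metrics = Metrics()
    events: list[StageEvent] = []
    outputs: list[FrameOutput] = []
    shape = tables.shape
    tracker = PedestalTracker(shape=shape, mode=cfg.pedestal_mode, alpha=cfg.pedestal_alpha)
    current_tables = tables

    results = _ingest(datagrams, shape, metrics)
    metrics.frames_seen = len(results)

    tick = 0
    for fr in results:
        if not fr.complete and (
            cfg.incomplete_policy == "drop" or _role(fr.frame_id) == "dark"
        ):
            metrics.incomplete += 1
            continue
        fc, cs, ce = tick + 1, tick + 2, tick + 3
        events.append(StageEvent("frame_complete", fr.frame_id, fc))
        events.append(StageEvent("compute_start", fr.frame_id, cs))
        if _role(fr.frame_id) == "dark":
            update_pedestal(tracker, fr.frame)
            current_tables = freeze_pedestal(tracker, tables)
            metrics.darks_absorbed += 1
            out = None
        else:
            metrics.lit_complete += 1
            accepted, out = _compute_lit(fr, current_tables, cfg)
            if accepted:
                metrics.accepted += 1
            else:
                metrics.rejected += 1
        events.append(StageEvent("compute_done", fr.frame_id, ce))
        tick = ce
        if out is not None:
            events.append(StageEvent("output_queued", fr.frame_id, ce))
            events.append(StageEvent("output_done", fr.frame_id, ce + OUTPUT_TICKS))
            outputs.append(out)
            metrics.bytes_out += _output_bytes(out.payload)
            tick = ce + OUTPUT_TICKS

    return PipelineReport(
        outputs=outputs,
        metrics=metrics,
        event_log=events,
        pedestal_count=tracker.count,
    )


def max_outputs_in_flight(events: list[StageEvent]) -> int:
    """Peak number of simultaneously in-flight output transfers in a log.

    A transfer is in flight during [output_queued, output_done) ticks.
    """
    intervals = {}
    for e in events:
        if e.kind == "output_queued":
            intervals[e.frame_id] = [e.tick, None]
        elif e.kind == "output_done":
            intervals[e.frame_id][1] = e.tick
    peak = 0
    spans = list(intervals.values())
    for start, _ in spans:
        concurrent = sum(1 for s, t in spans if s <= start < t)
        peak = max(peak, concurrent)
    return peak
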