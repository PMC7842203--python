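"""On-disk artifacts: frame stacks, CSR triplets, datagram streams, configs.

The canonical interchange is flat little-endian binary plus a JSON sidecar
(bit-exact and dependency-light); calibrations use HDF5 (see
:meth:`ssxpipe.calibration.GainTables.save`).  File extensions: ``.raw`` +
``.json`` frame stacks, ``.jfdg`` datagram streams, ``.csr`` + ``.json``
sparse images, ``metrics.json`` run metrics.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pydantic

from .datagram import DATAGRAM_SIZE, Datagram, parse, serialize
from .errors import FileFormatError, ValidationError
from .reduction import CSRImage, VetoConfig
from .pipeline import PipelineConfig
from .synthetic import EnergyFrame, RawFrame, SceneParams


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


# --- frame stacks ---------------------------------------------------------

_DTYPES = {"uint16": "<u2", "float32": "<f4"}


def write_frames(path, frames: Sequence[tuple[int, str, RawFrame | EnergyFrame]]) -> None:
    """Write a frame stack as flat binary + JSON sidecar.

    ``frames`` is a sequence of ``(frame_id, role, frame)``; all frames
    must share a shape and type (RawFrame -> uint16, EnergyFrame ->
    float32).  Round trips are bit-exact for RawFrame and exact at float32
    for EnergyFrame.
    """
    if not frames:
        raise ValidationError("refusing to write an empty frame stack")
    path = Path(path)
    first = frames[0][2]
    dtype = "uint16" if isinstance(first, RawFrame) else "float32"
    rows, cols = first.shape
    meta = {"rows": rows, "cols": cols, "dtype": dtype, "frames": []}
    with open(path, "wb") as f:
        for frame_id, role, fr in frames:
            arr = fr.words if isinstance(fr, RawFrame) else fr.values
            if arr.shape != (rows, cols):
                raise ValidationError("all frames in a stack must share a shape")
            f.write(np.ascontiguousarray(arr, dtype=_DTYPES[dtype]).tobytes())
            meta["frames"].append({"frame_id": int(frame_id), "role": role})
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_frames(path) -> list[tuple[int, str, RawFrame | EnergyFrame]]:
    """Read a frame stack written by :func:`write_frames`."""
    path = Path(path)
    try:
        meta = json.loads(_sidecar(path).read_text())
        rows, cols, dtype = meta["rows"], meta["cols"], meta["dtype"]
        entries = meta["frames"]
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise FileFormatError(f"unreadable frame sidecar for {path}: {exc}") from exc
    if dtype not in _DTYPES:
        raise FileFormatError(f"unknown frame dtype {dtype!r}")
    itemsize = 2 if dtype == "uint16" else 4
    per_frame = rows * cols * itemsize
    blob = path.read_bytes()
    if len(blob) != per_frame * len(entries):
        raise FileFormatError(
            f"{path} holds {len(blob)} bytes but the sidecar implies "
            f"{per_frame * len(entries)} ({len(entries)} x {per_frame})"
        )
    out = []
    for i, ent in enumerate(entries):
        arr = np.frombuffer(
            blob, dtype=_DTYPES[dtype], count=rows * cols, offset=i * per_frame
        ).reshape(rows, cols)
        if dtype == "uint16":
            frame: RawFrame | EnergyFrame = RawFrame(words=arr.astype(np.uint16))
        else:
            frame = EnergyFrame(values=arr.astype(np.float32))
        out.append((int(ent["frame_id"]), str(ent["role"]), frame))
    return out


# --- CSR triplets ---------------------------------------------------------


def write_csr(path, csr: CSRImage) -> None:
    """Write a CSR image as indptr||indices||data binary + JSON sidecar."""
    csr.validate()
    path = Path(path)
    with open(path, "wb") as f:
        f.write(np.ascontiguousarray(csr.indptr, dtype="<i8").tobytes())
        f.write(np.ascontiguousarray(csr.indices, dtype="<i4").tobytes())
        f.write(np.ascontiguousarray(csr.data, dtype="<f4").tobytes())
    _sidecar(path).write_text(
        json.dumps(
            {
                "rows": csr.shape[0],
                "cols": csr.shape[1],
                "nnz": csr.nnz,
                "capacity": csr.capacity,
                "threshold": csr.threshold,
            }
        )
    )


def read_csr(path) -> CSRImage:
    path = Path(path)
    try:
        meta = json.loads(_sidecar(path).read_text())
        rows, cols, nnz = meta["rows"], meta["cols"], meta["nnz"]
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise FileFormatError(f"unreadable CSR sidecar for {path}: {exc}") from exc
    blob = path.read_bytes()
    expect = (rows + 1) * 8 + nnz * 4 + nnz * 4
    if len(blob) != expect:
        raise FileFormatError(
            f"{path} holds {len(blob)} bytes, expected {expect} for "
            f"rows={rows}, nnz={nnz}"
        )
    indptr = np.frombuffer(blob, dtype="<i8", count=rows + 1)
    indices = np.frombuffer(blob, dtype="<i4", count=nnz, offset=(rows + 1) * 8)
    data = np.frombuffer(blob, dtype="<f4", count=nnz, offset=(rows + 1) * 8 + nnz * 4)
    try:
        return CSRImage(
            shape=(rows, cols),
            indptr=indptr.astype(np.int64),
            indices=indices.astype(np.int32),
            data=data.astype(np.float32),
            capacity=int(meta.get("capacity", nnz)),
            threshold=float(meta.get("threshold", 0.0)),
        )
    except ValidationError as exc:
        raise FileFormatError(f"structurally invalid CSR in {path}: {exc}") from exc


# --- datagram streams -----------------------------------------------------


def write_datagrams(path, datagrams: Sequence[Datagram]) -> None:
    """Raw concatenation of serialized datagrams (constant 8246-byte records)."""
    with open(path, "wb") as f:
        for d in datagrams:
            f.write(serialize(d))


def read_datagrams(path) -> list[Datagram]:
    blob = Path(path).read_bytes()
    if len(blob) % DATAGRAM_SIZE != 0:
        raise FileFormatError(
            f"{path}: size {len(blob)} is not a multiple of the "
            f"{DATAGRAM_SIZE}-byte datagram record"
        )
    return [
        parse(blob[i : i + DATAGRAM_SIZE]) for i in range(0, len(blob), DATAGRAM_SIZE)
    ]


# --- run configuration ----------------------------------------------------


class _Model(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class GeometryConfig(_Model):
    rows: int = 512
    cols: int = 1024


class CalibrationConfig(_Model):
    gain_levels: tuple[float, float, float] = (40.0, 2.0, 0.5)
    pedestal_levels: tuple[float, float, float] = (1000.0, 800.0, 700.0)
    jitter_fraction: float = 0.02


class SceneConfig(_Model):
    n_peaks: int = 40
    amplitude: float = 100.0
    peak_sigma: float = 1.2
    background_sigma: float = 1.0
    dark_noise_sigma: float = 5.0

    def to_params(self) -> SceneParams:
        return SceneParams(**self.model_dump())


class ChannelConfig(_Model):
    loss_probability: float = 0.0
    reorder_window: int = 0


class PipelineSection(_Model):
    buffer_depth: int = 2
    credits: int = 2
    mode: Literal["veto", "compress", "both"] = "veto"
    signal_threshold: float = 50.0
    min_peak_pixels: int = 5
    sparsify_threshold: float = 0.0
    csr_capacity: int | None = None
    incomplete_policy: Literal["drop", "nan"] = "drop"

    def to_config(self) -> PipelineConfig:
        return PipelineConfig(
            buffer_depth=self.buffer_depth,
            credits=self.credits,
            mode=self.mode,
            veto_cfg=VetoConfig(
                signal_threshold=self.signal_threshold,
                min_peak_pixels=self.min_peak_pixels,
            ),
            sparsify_threshold=self.sparsify_threshold,
            csr_capacity=self.csr_capacity,
            incomplete_policy=self.incomplete_policy,
        )


class RunConfig(_Model):
    """Whole-run configuration; round-trips losslessly through JSON."""

    seed: int = 0
    n_pairs: int = 4
    geometry: GeometryConfig = GeometryConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    scene: SceneConfig = SceneConfig()
    channel: ChannelConfig = ChannelConfig()
    pipeline: PipelineSection = PipelineSection()


def load_config(path) -> RunConfig:
    """Load and schema-validate a JSON run configuration.

    Unknown keys and type mismatches raise :class:`ValidationError`
    naming the offending key; absent keys take defaults.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValidationError(f"cannot read config {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(payload)
    except pydantic.ValidationError as exc:
        locs = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ValidationError(f"invalid config {path}: offending key(s): {locs}") from exc


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.model_dump(), indent=1))
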