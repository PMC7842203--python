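"""Compute kernels: raw-to-energy conversion, Bragg-pixel veto, CSR
compression — each with a scalar brute-force twin used as an oracle.

The conversion reads the gain level k from the two MSBs of each raw word
and computes

    energy = (value14 - pedestal[k]) / gain[k]

in 32-bit float, exactly one integer subtraction and one floating-point
division per pixel.  The veto counts pixels strictly above a signal
threshold (a crude Bragg-peak proxy, no noise correction or outlier
removal) and accepts a frame when the count reaches a minimum.  As an
alternative to rejection, frames are sparsified to CSR with the indptr
built as an exclusive prefix sum of per-row retained counts into storage
whose capacity is fixed a priori from the expected sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import RAW_MAX, GainTables
from .errors import (
    CapacityOverflowError,
    ShapeMismatchError,
    ValidationError,
)
from .synthetic import GAIN_BIT_DECODE, EnergyFrame, RawFrame

# --- raw-data correction --------------------------------------------------


def correct_frame(
    raw: RawFrame, tables: GainTables, invalid: str = "nan"
) -> EnergyFrame:
    """Convert a raw frame to energies using per-pixel three-gain tables.

    Pixels carrying the reserved gain-bit pattern 0b10 are masked to NaN by
    default (``invalid="nan"``) or raise with ``invalid="error"``.  Output
    is float32; negative energies (noise below pedestal) are legal and not
    clipped.
    """
    if invalid not in ("nan", "error"):
        raise ValidationError(f"unknown invalid-bit policy {invalid!r}")
    words = np.asarray(raw.words)
    if words.shape != tables.shape:
        raise ShapeMismatchError(
            f"raw shape {words.shape} != calibration shape {tables.shape}"
        )
    bits = words >> 14
    level = GAIN_BIT_DECODE[bits]
    bad = level < 0
    if bad.any() and invalid == "error":
        raise ValidationError(
            f"{int(bad.sum())} pixel(s) carry the reserved gain-bit pattern 0b10"
        )
    k = np.where(bad, 0, level).astype(np.intp)
    value = (words & (RAW_MAX - 1)).astype(np.float32)
    ped = np.take_along_axis(tables.pedestal, k[None], axis=0)[0]
    gain = np.take_along_axis(tables.gain, k[None], axis=0)[0]
    energy = (value - ped) / gain  # float32 throughout
    if bad.any():
        energy = energy.copy()
        energy[bad] = np.nan
    return EnergyFrame(values=energy.astype(np.float32, copy=False))


@dataclass(frozen=True)
class OpCounts:
    """Arithmetic operations performed by the instrumented scalar kernel."""

    subtractions: int
    divisions: int


def scalar_correct_frame(raw: RawFrame, tables: GainTables) -> tuple[EnergyFrame, OpCounts]:
    """Instrumented scalar reference for :func:`correct_frame`.

    Processes pixels one by one in float32 arithmetic, counting every
    integer subtraction and floating-point division it performs: exactly
    one of each per valid pixel.  Agrees bitwise with the vectorized
    kernel (both do a single float32 subtraction and division per pixel).
    """
    words = np.asarray(raw.words)
    if words.shape != tables.shape:
        raise ShapeMismatchError(
            f"raw shape {words.shape} != calibration shape {tables.shape}"
        )
    rows, cols = words.shape
    flat_words = words.ravel().tolist()
    ped_planes = [tables.pedestal[k].ravel() for k in range(3)]
    gain_planes = [tables.gain[k].ravel() for k in range(3)]
    decode = {0: 0, 1: 1, 3: 2}
    out = np.empty(rows * cols, dtype=np.float32)
    f32 = np.float32
    n_sub = 0
    n_div = 0
    for i, w in enumerate(flat_words):
        k = decode.get(w >> 14)
        if k is None:
            out[i] = np.nan
            continue
        value = w & 0x3FFF
        diff = f32(value) - ped_planes[k][i]  # one 16-bit integer subtraction
        n_sub += 1
        out[i] = diff / gain_planes[k][i]  # one 32-bit float division
        n_div += 1
    return (
        EnergyFrame(values=out.reshape(rows, cols)),
        OpCounts(subtractions=n_sub, divisions=n_div),
    )


# --- veto -----------------------------------------------------------------


@dataclass(frozen=True)
class VetoConfig:
    """Two-threshold hit-finding rule.

    ``signal_threshold``: energy a pixel must strictly exceed to count as
    a Bragg-peak pixel.  ``min_peak_pixels``: minimum such count for the
    frame to be accepted.  No physical defaults exist; both must be tuned
    to the scene for any scientific use.
    """

    signal_threshold: float = 50.0
    min_peak_pixels: int = 5

    def __post_init__(self) -> None:
        if not np.isfinite(self.signal_threshold):
            raise ValidationError("signal_threshold must be finite")
        if self.min_peak_pixels < 0:
            raise ValidationError("min_peak_pixels must be >= 0")


def count_peak_pixels(energy: EnergyFrame, signal_threshold: float) -> int:
    """Number of pixels strictly above the signal threshold (NaNs never count)."""
    if not np.isfinite(signal_threshold):
        raise ValidationError("signal_threshold must be finite")
    with np.errstate(invalid="ignore"):
        return int(np.count_nonzero(energy.values > signal_threshold))


def veto(energy: EnergyFrame, cfg: VetoConfig) -> tuple[bool, int]:
    """Accept the frame iff its peak-pixel count reaches the minimum."""
    count = count_peak_pixels(energy, cfg.signal_threshold)
    return count >= cfg.min_peak_pixels, count


# --- CSR compression ------------------------------------------------------


@dataclass(frozen=True)
class CSRImage:
    """Compressed sparse row image with a-priori storage capacity.

    ``indptr`` (int64, len rows+1) is the exclusive prefix sum of per-row
    stored counts; ``indices`` (int32) are column positions, strictly
    increasing within each row; ``data`` (float32) are the stored values.
    """

    shape: tuple[int, int]
    indptr: np.ndarray
    indices: np.ndarray
    data: np.ndarray
    capacity: int
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rows, cols = self.shape
        indptr, indices, data = self.indptr, self.indices, self.data
        if len(indptr) != rows + 1 or indptr[0] != 0:
            raise ValidationError("indptr must have length rows+1 and start at 0")
        if np.any(np.diff(indptr) < 0):
            raise ValidationError("indptr must be non-decreasing")
        nnz = int(indptr[-1])
        if len(indices) != nnz or len(data) != nnz:
            raise ValidationError(
                f"indices/data lengths ({len(indices)}/{len(data)}) must equal "
                f"indptr[rows] = {nnz}"
            )
        if nnz > self.capacity:
            raise ValidationError(
                f"stored count {nnz} exceeds declared capacity {self.capacity}"
            )
        if nnz and (indices.min() < 0 or indices.max() >= cols):
            raise ValidationError(f"column indices must lie in [0, {cols})")
        if nnz > 1:
            d = np.diff(indices.astype(np.int64))
            row_breaks = np.zeros(nnz - 1, dtype=bool)
            starts = indptr[1:-1]
            starts = starts[(starts > 0) & (starts < nnz)]
            row_breaks[np.asarray(starts, dtype=np.int64) - 1] = True
            if np.any(d[~row_breaks] <= 0):
                raise ValidationError("indices must be strictly increasing per row")

    @property
    def nnz(self) -> int:
        return int(self.indptr[-1])


def default_csr_capacity(shape: tuple[int, int], fraction: float = 0.02) -> int:
    """A-priori CSR capacity: a fixed fraction (default 2%) of pixel count."""
    return int(np.ceil(shape[0] * shape[1] * fraction))


def csr_compress(
    energy: EnergyFrame,
    sparsify_threshold: float = 0.0,
    capacity: int | None = None,
) -> CSRImage:
    """Sparsify to CSR, keeping pixels strictly above the threshold.

    The indptr array is the exclusive cumulative sum of per-row retained
    counts (the scan step of the classical parallel scan/reduction
    construction).  If the retained count exceeds ``capacity`` the
    compression fails before any partial write.  NaN pixels are never
    stored.
    """
    vals = np.asarray(energy.values)
    rows, cols = vals.shape
    if capacity is None:
        capacity = default_csr_capacity((rows, cols))
    if capacity < 0:
        raise ValidationError("capacity must be >= 0")
    with np.errstate(invalid="ignore"):
        mask = vals > sparsify_threshold  # NaN compares False
    row_counts = mask.sum(axis=1)
    nnz = int(row_counts.sum())
    if nnz > capacity:
        raise CapacityOverflowError(required=nnz, capacity=capacity)
    indptr = np.zeros(rows + 1, dtype=np.int64)
    np.cumsum(row_counts, out=indptr[1:])
    r_idx, c_idx = np.nonzero(mask)  # row-major: columns ascend within rows
    return CSRImage(
        shape=(rows, cols),
        indptr=indptr,
        indices=c_idx.astype(np.int32),
        data=vals[r_idx, c_idx].astype(np.float32),
        capacity=int(capacity),
        threshold=float(sparsify_threshold),
    )


def csr_decompress(csr: CSRImage) -> EnergyFrame:
    """Densify: stored values at stored positions, zeros elsewhere."""
    csr.validate()
    rows, cols = csr.shape
    out = np.zeros((rows, cols), dtype=np.float32)
    row_ids = np.repeat(np.arange(rows), np.diff(csr.indptr))
    out[row_ids, csr.indices] = csr.data
    return EnergyFrame(values=out)
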