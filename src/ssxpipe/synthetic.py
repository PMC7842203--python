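"""Synthetic diffraction scenes, raw-word encoding and chopper sequences.

This module is the package's stand-in for a detector.  It renders simple
ground-truth scenes (isotropic Gaussian Bragg spots on Gaussian background),
folds them through the adaptive-gain front end — auto-ranging gain
selection, pedestal addition, 14-bit digitization, gain bits in the two
MSBs — and emits chopper-interleaved dark/lit acquisition sequences with
the pre-encoding ground truth retained for every lit frame.

The gain-bit encoding is level 0 -> 0b00, level 1 -> 0b01, level 2 -> 0b11;
the pattern 0b10 is reserved and never produced, which gives downstream
code a testable invalid word.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .calibration import RAW_MAX, GainTables
from .errors import SaturationError, ShapeMismatchError, ValidationError

#: gain level index -> two-bit code in the raw word MSBs
GAIN_BIT_CODES = np.array([0b00, 0b01, 0b11], dtype=np.uint16)
#: two-bit code -> gain level; -1 marks the reserved pattern 0b10
GAIN_BIT_DECODE = np.array([0, 1, -1, 2], dtype=np.int8)

VALUE_MASK = np.uint16(RAW_MAX - 1)


def substream(seed: int, label: str) -> np.random.Generator:
    """Named, independent RNG substream derived from one top-level seed.

    All randomness in the package fans out from a single seed through
    labelled substreams ("scene", "darks", "channel", ...) so any stage is
    independently replayable.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


@dataclass(frozen=True)
class EnergyFrame:
    """Corrected / pre-encoding image in ADU-normalized energy units."""

    values: np.ndarray  # float32, (rows, cols)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RawFrame:
    """Raw detector image: per-pixel 16-bit word = (gain_bits << 14) | value14."""

    words: np.ndarray  # uint16, (rows, cols)

    @property
    def shape(self) -> tuple[int, int]:
        return self.words.shape  # type: ignore[return-value]

    @property
    def value14(self) -> np.ndarray:
        return self.words & VALUE_MASK

    @property
    def gain_bits(self) -> np.ndarray:
        return self.words >> 14


@dataclass(frozen=True)
class Peak:
    row: float
    col: float
    amplitude: float


@dataclass(frozen=True)
class GroundTruth:
    energy: EnergyFrame
    peaks: tuple[Peak, ...]


@dataclass(frozen=True)
class SequenceFrame:
    frame_id: int
    role: str  # "dark" | "lit"
    raw: RawFrame


@dataclass(frozen=True)
class AcquisitionSequence:
    """Strictly alternating dark/lit frame stream with retained ground truth."""

    frames: tuple[SequenceFrame, ...]
    ground_truth: dict[int, GroundTruth] = field(default_factory=dict)


@dataclass(frozen=True)
class SceneParams:
    """Scene and noise parameters for synthetic acquisition.

    Defaults model a sparse still-diffraction snapshot: a few tens of
    sharp spots well above a unit-sigma background, with ~5 ADU of
    electronic noise on the darks.
    """

    n_peaks: int = 40
    amplitude: float = 100.0
    peak_sigma: float = 1.2
    background_sigma: float = 1.0
    dark_noise_sigma: float = 5.0


def generate_peaks_image(
    shape: tuple[int, int],
    n_peaks: int,
    amplitude: float,
    peak_sigma: float,
    background_sigma: float,
    seed: int,
) -> tuple[EnergyFrame, tuple[Peak, ...]]:
    """Render Gaussian spots on zero-mean Gaussian background.

    Spot centers are drawn uniformly over the frame; every spot is an
    isotropic 2-D Gaussian of the given amplitude and width.  The returned
    peak list is the scene ground truth.  Deterministic under ``seed``.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValidationError(f"shape must be positive, got {(rows, cols)}")
    if n_peaks < 0:
        raise ValidationError("n_peaks must be >= 0")
    if n_peaks > rows * cols:
        raise ValidationError(
            f"n_peaks = {n_peaks} exceeds the pixel count {rows * cols}"
        )
    if amplitude <= 0:
        raise ValidationError("amplitude must be > 0")
    if peak_sigma < 0 or background_sigma < 0:
        raise ValidationError("sigmas must be >= 0")

    rng = np.random.default_rng(seed)
    if background_sigma > 0:
        img = rng.normal(0.0, background_sigma, (rows, cols))
    else:
        img = np.zeros((rows, cols))

    peaks = []
    # spots are rendered on a local window of +-5 sigma; beyond that the
    # Gaussian tail is below float32 resolution at any sane amplitude
    half = max(1, int(np.ceil(5 * peak_sigma))) if peak_sigma > 0 else 0
    for _ in range(n_peaks):
        r0 = rng.uniform(0, rows)
        c0 = rng.uniform(0, cols)
        peaks.append(Peak(row=r0, col=c0, amplitude=amplitude))
        if peak_sigma == 0:
            img[min(int(r0), rows - 1), min(int(c0), cols - 1)] += amplitude
            continue
        rlo, rhi = max(0, int(r0) - half), min(rows, int(r0) + half + 1)
        clo, chi = max(0, int(c0) - half), min(cols, int(c0) + half + 1)
        rr = np.arange(rlo, rhi)[:, None] - r0
        cc = np.arange(clo, chi)[None, :] - c0
        img[rlo:rhi, clo:chi] += amplitude * np.exp(
            -(rr**2 + cc**2) / (2.0 * peak_sigma**2)
        )
    return EnergyFrame(values=img.astype(np.float32)), tuple(peaks)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (fixed encoder rule)."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def encode_raw(
    energy: EnergyFrame, tables: GainTables, saturation: str = "error"
) -> RawFrame:
    """Digitize an energy image into gain-tagged 16-bit raw words.

    Auto-ranging: per pixel, the selected gain level ``k`` is the smallest
    index for which ``round(energy * gain[k] + pedestal[k])`` fits the
    14-bit range ``[0, 2**14)``; the word is ``(bits(k) << 14) | value``.
    If no level fits, a :class:`SaturationError` is raised, or with
    ``saturation="clamp"`` the pixel is clamped into level 2.
    """
    if saturation not in ("error", "clamp"):
        raise ValidationError(f"unknown saturation policy {saturation!r}")
    vals = np.asarray(energy.values)
    if vals.shape != tables.shape:
        raise ShapeMismatchError(
            f"energy shape {vals.shape} != calibration shape {tables.shape}"
        )
    if not np.all(np.isfinite(vals)):
        raise ValidationError("energy frame contains non-finite values")

    # candidate digitized value at each of the three levels
    cand = _round_half_away(
        vals[None].astype(np.float64) * tables.gain.astype(np.float64)
        + tables.pedestal.astype(np.float64)
    )
    fits = (cand >= 0) & (cand < RAW_MAX)
    level = np.argmax(fits, axis=0)  # first fitting level (argmax of bools)
    none_fit = ~fits.any(axis=0)
    if none_fit.any():
        if saturation == "error":
            n = int(none_fit.sum())
            raise SaturationError(
                f"{n} pixel(s) unrepresentable at every gain level"
            )
        level = np.where(none_fit, 2, level)

    value = np.take_along_axis(cand, level[None], axis=0)[0]
    value = np.clip(value, 0, RAW_MAX - 1).astype(np.uint16)
    words = (GAIN_BIT_CODES[level].astype(np.uint16) << 14) | value
    return RawFrame(words=words)


def generate_dark(tables: GainTables, noise_sigma: float, seed: int) -> RawFrame:
    """Emit one dark frame: level-0 pedestal plus Gaussian read noise."""
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rows, cols = tables.shape
    v = tables.pedestal[0].astype(np.float64)
    if noise_sigma > 0:
        v = v + rng.normal(0.0, noise_sigma, (rows, cols))
    value = np.clip(_round_half_away(v), 0, RAW_MAX - 1).astype(np.uint16)
    return RawFrame(words=value)  # gain bits 0b00 == level 0


def make_sequence(
    n_pairs: int,
    tables: GainTables,
    scene_params: SceneParams | None = None,
    seed: int = 0,
) -> AcquisitionSequence:
    """Build a chopper-interleaved acquisition: dark, lit, dark, lit, ...

    Emits ``2 * n_pairs`` frames with frame_ids counting from 0.  Every lit
    frame encodes a freshly drawn peak scene whose pre-encoding energy
    image and peak list are retained as ground truth; darks carry none.
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    sp = scene_params or SceneParams()
    scene_rng = substream(seed, "scene")
    dark_rng = substream(seed, "darks")

    frames: list[SequenceFrame] = []
    truth: dict[int, GroundTruth] = {}
    for pair in range(n_pairs):
        dark_id, lit_id = 2 * pair, 2 * pair + 1
        dark = generate_dark(
            tables, sp.dark_noise_sigma, seed=int(dark_rng.integers(0, 2**31))
        )
        frames.append(SequenceFrame(frame_id=dark_id, role="dark", raw=dark))

        energy, peaks = generate_peaks_image(
            tables.shape,
            sp.n_peaks,
            sp.amplitude,
            sp.peak_sigma,
            sp.background_sigma,
            seed=int(scene_rng.integers(0, 2**31)),
        )
        raw = encode_raw(energy, tables)
        frames.append(SequenceFrame(frame_id=lit_id, role="lit", raw=raw))
        truth[lit_id] = GroundTruth(energy=energy, peaks=peaks)
    return AcquisitionSequence(frames=tuple(frames), ground_truth=truth)
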