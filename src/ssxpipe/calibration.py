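"""Per-pixel three-gain calibration tables and dark-frame pedestal tracking.

An adaptive-gain pixel detector digitizes each pixel in one of three
amplifier regimes ("gain levels").  Converting a raw 14-bit sample back to
deposited energy requires, per pixel and per level, a pedestal offset (the
dark baseline, in ADU) and a gain factor (ADU per energy unit) — six
coefficients per pixel.  Level 0 is the highest gain: it has the largest
gain factor and is the regime a pixel sits in at low signal, which is why
darks only inform the level-0 pedestal.

Pedestals drift, so they are re-estimated online from dark frames acquired
while a chopper blocks the beam.  :class:`PedestalTracker` absorbs those
darks either as a running mean (exact, for stable conditions) or as an
exponential moving average (for drift tracking during long runs);
:func:`freeze_pedestal` stamps the current estimate into a table set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import ShapeMismatchError, ValidationError

RAW_MAX = 1 << 14  # 14-bit sample range, exclusive upper bound
N_GAIN_LEVELS = 3


@dataclass(frozen=True)
class GainTables:
    """Per-pixel correction coefficients for the three gain levels.

    Attributes
    ----------
    pedestal
        float32 array of shape ``(3, rows, cols)``, ADU.  ``pedestal[k]``
        is the dark offset at gain level ``k``.
    gain
        float32 array of shape ``(3, rows, cols)``, ADU per energy unit.
        Strictly decreasing in ``k`` at every pixel (level 0 = highest gain).
    """

    pedestal: np.ndarray
    gain: np.ndarray

    def __post_init__(self) -> None:
        ped, gn = np.asarray(self.pedestal), np.asarray(self.gain)
        if ped.ndim != 3 or ped.shape[0] != N_GAIN_LEVELS or ped.shape != gn.shape:
            raise ValidationError(
                f"pedestal/gain must both have shape (3, rows, cols); got "
                f"{ped.shape} and {gn.shape}"
            )
        if not np.all(gn > 0):
            raise ValidationError("gain factors must be strictly positive")
        if not (np.all(gn[0] > gn[1]) and np.all(gn[1] > gn[2])):
            raise ValidationError("gain must be strictly decreasing with level")
        if not (np.all(ped >= 0) and np.all(ped < RAW_MAX)):
            raise ValidationError(f"pedestals must lie in [0, {RAW_MAX})")

    @property
    def shape(self) -> tuple[int, int]:
        """Pixel-grid dimensions ``(rows, cols)``."""
        return self.pedestal.shape[1], self.pedestal.shape[2]

    @property
    def coefficient_count(self) -> int:
        """Total stored coefficients: rows x cols x 3 levels x 2 tables."""
        return self.pedestal.size + self.gain.size

    def with_pedestal0(self, estimate: np.ndarray) -> "GainTables":
        """Return a copy with the level-0 pedestal plane replaced."""
        ped = self.pedestal.copy()
        ped[0] = np.asarray(estimate, dtype=np.float32)
        return GainTables(pedestal=ped, gain=self.gain)

    # --- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Write tables to an HDF5 file (float32 datasets + shape attrs)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("pedestal", data=self.pedestal.astype("<f4"))
            f.create_dataset("gain", data=self.gain.astype("<f4"))
            f.attrs["rows"], f.attrs["cols"] = self.shape
            f.attrs["producer"] = "ssxpipe"

    @classmethod
    def load(cls, path) -> "GainTables":
        with h5py.File(path, "r") as f:
            return cls(
                pedestal=np.asarray(f["pedestal"], dtype=np.float32),
                gain=np.asarray(f["gain"], dtype=np.float32),
            )


def make_calibration(
    shape: tuple[int, int],
    gain_levels: tuple[float, float, float] = (40.0, 2.0, 0.5),
    pedestal_levels: tuple[float, float, float] = (1000.0, 800.0, 700.0),
    jitter_fraction: float = 0.02,
    seed: int = 0,
) -> GainTables:
    """Build synthetic per-pixel calibration tables.

    Each per-pixel coefficient is the corresponding level scalar perturbed
    multiplicatively by uniform jitter in ``[1 - j, 1 + j]``, emulating the
    pixel-to-pixel dispersion of real sensor calibrations.  Deterministic
    under ``seed``.

    Parameters
    ----------
    shape
        ``(rows, cols)`` of the pixel grid; both positive.
    gain_levels
        Three strictly decreasing positive gain factors (ADU / energy unit).
    pedestal_levels
        Three pedestal offsets in ``[0, 2**14)`` ADU.
    jitter_fraction
        Relative half-width ``j`` of the multiplicative jitter, in [0, 0.5).
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValidationError(f"shape must be positive, got {(rows, cols)}")
    gains = tuple(float(g) for g in gain_levels)
    peds = tuple(float(p) for p in pedestal_levels)
    if len(gains) != N_GAIN_LEVELS or len(peds) != N_GAIN_LEVELS:
        raise ValidationError("exactly three gain and pedestal levels required")
    if any(g <= 0 for g in gains):
        raise ValidationError("gain levels must be positive")
    if not (gains[0] > gains[1] > gains[2]):
        raise ValidationError("gain levels must be strictly decreasing")
    if any(not 0 <= p < RAW_MAX for p in peds):
        raise ValidationError(f"pedestal levels must lie in [0, {RAW_MAX})")
    if not 0 <= jitter_fraction < 0.5:
        raise ValidationError("jitter_fraction must lie in [0, 0.5)")

    rng = np.random.default_rng(seed)
    jit = lambda: rng.uniform(1 - jitter_fraction, 1 + jitter_fraction, (rows, cols))
    gain = np.stack([g * jit() for g in gains]).astype(np.float32)
    ped = np.stack([p * jit() for p in peds]).astype(np.float32)
    # multiplicative jitter never reorders levels for j < 0.5 with the
    # default 40/2/0.5 spacing, but guard against pathological inputs
    ped = np.clip(ped, 0, np.nextafter(np.float32(RAW_MAX), np.float32(0)))
    return GainTables(pedestal=ped, gain=gain)


@dataclass
class PedestalTracker:
    """Online per-pixel pedestal estimator for gain level 0.

    ``mode="running_mean"`` keeps the exact arithmetic mean of absorbed dark
    values per pixel; ``mode="ema"`` applies an exponential moving average
    with weight ``alpha`` (drift tracking).  Pixels whose gain bits decode
    to a level other than 0 are skipped — isolated pixels may saturate even
    in a dark frame.
    """

    shape: tuple[int, int]
    mode: str = "running_mean"
    alpha: float = 0.05
    count: int = 0
    estimate: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _pixel_count: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mode not in ("running_mean", "ema"):
            raise ValidationError(f"unknown pedestal mode {self.mode!r}")
        if self.mode == "ema" and not 0 < self.alpha <= 1:
            raise ValidationError("alpha must lie in (0, 1] for EMA mode")
        if self.estimate is None:
            self.estimate = np.zeros(self.shape, dtype=np.float64)
        if self._pixel_count is None:
            self._pixel_count = np.zeros(self.shape, dtype=np.int64)


def update_pedestal(tracker: PedestalTracker, dark) -> PedestalTracker:
    """Absorb one dark frame into the tracker (in place; returns it).

    Only pixels whose two gain bits decode to level 0 contribute; their
    14-bit values enter the running mean / EMA.  ``tracker.count`` counts
    absorbed frames regardless of per-pixel skips.
    """
    words = np.asarray(dark.words)
    if words.shape != tuple(tracker.shape):
        raise ShapeMismatchError(
            f"dark shape {words.shape} != tracker shape {tuple(tracker.shape)}"
        )
    level0 = (words >> 14) == 0b00
    value = (words & (RAW_MAX - 1)).astype(np.float64)

    if tracker.mode == "running_mean":
        n = tracker._pixel_count + level0
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = np.where(level0, (value - tracker.estimate) / np.maximum(n, 1), 0.0)
        tracker.estimate = tracker.estimate + delta
        tracker._pixel_count = n
    else:  # ema
        first = level0 & (tracker._pixel_count == 0)
        upd = tracker.estimate + tracker.alpha * (value - tracker.estimate)
        tracker.estimate = np.where(first, value, np.where(level0, upd, tracker.estimate))
        tracker._pixel_count = tracker._pixel_count + level0
    tracker.count += 1
    return tracker


def freeze_pedestal(tracker: PedestalTracker, tables: GainTables) -> GainTables:
    """Stamp the tracker's estimate into the level-0 pedestal plane.

    Levels 1 and 2 are left untouched: their pedestals are taken as
    constant, since darks only sample the high-gain regime.  Requires at
    least one absorbed dark.
    """
    if tracker.count < 1:
        raise ValidationError("cannot freeze a pedestal tracker with no darks absorbed")
    if tuple(tracker.shape) != tables.shape:
        raise ShapeMismatchError(
            f"tracker shape {tuple(tracker.shape)} != tables shape {tables.shape}"
        )
    return tables.with_pedestal0(tracker.estimate)
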