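# Methods

`ssxpipe` emulates the logic of an online serial-crystallography (SSX)
reduction chain for an adaptive-gain pixel detector.  Everything here is a
desk-scale software model: the package reproduces the chain's *semantics* —
formats, arithmetic, ordering, flow control — not its hardware throughput.

## Detector and correction model

Each pixel digitizes in one of three amplifier regimes ("gain levels").  A
raw sample is a 16-bit word: the two most-significant bits encode the gain
level, the remaining 14 bits the value in arbitrary detector units (ADU).
The bit map is level 0 → `0b00`, level 1 → `0b01`, level 2 → `0b11`;
`0b10` is reserved and never produced by the encoder, which gives every
downstream component a well-defined invalid pattern.  By default the
corrector maps `0b10` pixels to NaN (configurable to an error); NaN pixels
never count as peak pixels and are never stored in CSR output.

Conversion to energy is, per pixel, with k the decoded level:

    energy = (value14 − pedestal_k) / gain_k

one 16-bit integer subtraction and one 32-bit float division per pixel —
8 million scalar operations for a 4M frame.  Level 0 is the *highest* gain
(largest gain factor, hence largest divisor): it is the regime a low-signal
pixel sits in, which is why dark frames — acquired while the chopper blocks
the beam — inform only the level-0 pedestal.  Pedestals for levels 1 and 2
are treated as constant.  Negative energies (noise below pedestal) are legal
outputs and are not clipped.

The vectorized corrector and the instrumented scalar reference both perform
the subtraction and division in float32, so they agree bitwise; the scalar
twin additionally counts its operations and serves as the oracle.

### Calibration tables

Six coefficients per pixel (3 pedestals + 3 gains), stored as float32
`(3, rows, cols)` arrays — 24 million values for a 4M detector.  The
synthetic calibration perturbs the level scalars multiplicatively by uniform
jitter in [1−j, 1+j] (default j = 0.02), emulating pixel-to-pixel dispersion.
Default level scalars are gains (40, 2, 0.5) ADU per energy unit and
pedestals (1000, 800, 700) ADU.  The gain magnitudes are arbitrary: no units
are claimed for the energy axis, only the strict decrease across levels and
the ~10–100× spacing typical of adaptive-gain front ends matter to the
model.

### Pedestal tracking

`PedestalTracker` absorbs darks either as an exact per-pixel running mean
(default; equals the brute-force stack mean to float64 accumulation
accuracy) or as an EMA with weight `alpha` (default 0.05) for drift tracking
during continuous operation.  Dark pixels whose gain bits are not level 0
are skipped, not errors: isolated pixels can saturate even beam-off.
`freeze_pedestal` stamps the estimate into the level-0 plane of a table set
and requires at least one absorbed dark.

## Scene synthesis and digitization

Lit frames are zero-mean Gaussian background (σ = 1 energy unit by default)
plus `n_peaks` isotropic Gaussian spots (default 40 spots, amplitude 100,
σ = 1.2 px) at uniform random centers — a deliberately simple stand-in for
sparse still-diffraction snapshots.  It does *not* model crystal lattices,
Ewald-sphere geometry, Poisson counting statistics, module gaps or bad-pixel
maps; passing tests therefore demonstrate correctness of the reduction
chain's mechanics, not detector-grade realism.  Dark frames are the level-0
pedestal plus Gaussian read noise (σ = 5 ADU by default).

Digitization auto-ranges: the selected level is the smallest k for which
`round(energy × gain_k + pedestal_k)` lands in [0, 2¹⁴).  The lower bound is
required as well as the upper one, since a 14-bit value cannot be negative.
Rounding is half-away-from-zero, fixed so the ±0.5 ADU quantization bound —
and hence the encode→correct round-trip bound of 0.5/gain_k per pixel — is
exact.  A signal representable at no level raises a saturation error by
default, or clamps into level 2 when configured (`saturation="clamp"`).
Acquisition sequences strictly alternate dark, lit, … with frame ids from 0,
so frame-id parity (even = dark) identifies the role downstream.

All randomness fans out from one top-level seed through named substreams
(scene, darks, channel), so any stage is independently replayable.

## Datagram dialect and assembly

Frames are split row-major into 8192-byte payloads (four 1024-pixel lines in
the canonical geometry): a 512×1024 frame yields exactly 128 datagrams.  The
invented 54-byte little-endian header carries a globally incrementing packet
sequence number (loss detection), the destination byte offset (one-sided
placement), and on the final packet of each frame a completion flag plus a
32-bit immediate value — so a full datagram serializes to exactly 8246
bytes.  The assembler writes each payload at its destination offset, making
the result a pure function of the datagram *set*; identical duplicates are
idempotently accepted, conflicting duplicates are an integrity error, and
the completion event is surfaced only when no packet is missing.

The channel model drops each packet independently with probability `loss`
(the loss decisions are the first n draws of the seeded generator, making
the dropped set exactly replayable) and then applies a bounded-window
shuffle: survivor i is sorted by key `i + U(0,1)·window`, which displaces no
packet by more than `window` positions and never duplicates or corrupts.

## Reduction kernels

The veto counts pixels whose energy *strictly* exceeds `signal_threshold`
(strict comparison fixed so brute-force oracles are unambiguous) and accepts
a frame when the count reaches `min_peak_pixels` — a deliberately crude hit
finder with no noise correction or outlier removal.  No physically
meaningful default thresholds exist; the defaults (50 energy units, 5
pixels) suit the synthetic scenes only and must be user-set for any real
use.  Veto and CSR operate on the corrected energy frame, not raw ADU.

CSR sparsification keeps pixels strictly above `sparsify_threshold`:
`indptr` is the exclusive prefix sum of per-row retained counts, `indices`/
`data` follow in row-major order.  Storage capacity is fixed a priori
(default 2 % of the pixel count — a sparsity assumption, deliberately a
config knob); exceeding it fails with the required capacity named, before
any partial write.  Whether the prefix sum runs literally in parallel is an
implementation freedom; here it is a vectorized cumulative sum.

## Pipeline orchestration

The runner emulates a three-stage loop — (1) ingest/assemble, (2) correct +
veto or compress, (3) conditional output — as a deterministic event-driven
scheduler over logical ticks rather than real threads: the testable surface
of the overlap is ordering and equivalence, not wall-clock speed.  Per
frame the event log records `frame_complete < compute_start < compute_done ≤
output_queued ≤ output_done`.  Compute of a frame starts strictly after its
completion event; at most `buffer_depth` frames (default 2, double
buffering) sit assembled-but-uncomputed, so with depth ≥ 2 the ingest of
frame n+2 overlaps the compute of frame n+1 in the log.  Output transfers
occupy 3 ticks — longer than the 1-tick compute stage, so back-to-back
accepted frames genuinely contend for credits — and at most `credits`
transfers are in flight at once; when none is free the source blocks and a
`credit_wait` event is logged (blocking back-pressure is this emulator's
choice; drop-on-no-credit would be equally defensible in hardware).

Darks update the pedestal tracker at their compute slot and produce no
output; the updated pedestal applies only to frames computed afterwards (no
retroactive correction, mirroring online operation).  Incomplete frames are
dropped from compute by default ("a receiver cannot wait forever"),
configurable to process-with-gap with NaN in the missing payload zones; an
incomplete dark is always dropped so a partial frame cannot poison the
pedestal estimate.  Modes: `veto` emits accepted energy frames, `compress`
emits CSR for every complete lit frame (compression replaces rejection),
`both` emits CSR for accepted frames only.

`run_sequential_reference` implements the identical contract as a plain
one-frame-at-a-time loop with no scheduler.  The equivalence tests assert
bit-identical outputs and metrics between the two runners across seeded
scenarios spanning loss rates, modes, buffer depths and credit counts.

## Numerical and testing choices

- Energies, gains and pedestals are float32; pedestal accumulation is
  float64.  Round-trip tests allow 10⁻³ ADU of slack beyond the 0.5/gain
  quantization bound for float32 arithmetic.
- Test and acceptance problem sizes are desk-scale by design: 8×1024 or
  64×1024 frames (1–16 datagrams each) everywhere except the cardinality and
  operation-count checks, which run at the full 4M-pixel scale because they
  are the quantities being measured.
- The statistical pedestal-recovery check uses N = 100 darks at σ = 5 ADU
  and requires |estimate − truth| ≤ 5σ/√N on ≥ 99 % of pixels; with the
  ~0.5 ADU standard error this bound sits at ≈ 5 standard errors, so the
  check is seed-stable without being vacuous.
- File formats are flat little-endian binary + JSON sidecar (frames, CSR,
  datagram streams) for bit-exact, dependency-light interchange; calibration
  uses HDF5.  Round trips are exact at the declared precisions.

## Known limitations

No real networking or RDMA verbs, no GPU execution, no wall-clock
benchmarking; the datagram dialect is an emulation format, not
vendor-compatible; the scene model is statistical, not crystallographic; no
energy calibration in physical units; no peak clustering or
noise-model-aware thresholding (the veto is intentionally simplistic).
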