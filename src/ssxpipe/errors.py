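"""Exception hierarchy shared across the package.

Validation problems (bad parameters, shape mismatches, malformed configs)
derive from :class:`ValidationError`; data-integrity problems (conflicting
duplicate packets, corrupt files, CSR capacity overflow) derive from
:class:`IntegrityError`.  The CLI maps these onto exit codes 2 and 3.
"""

from __future__ import annotations


class SSXError(Exception):
    """Base class for all package errors."""


class ValidationError(SSXError, ValueError):
    """A parameter, shape or configuration violates its contract."""


class ShapeMismatchError(ValidationError):
    """Two objects that must share a pixel grid do not."""


class SaturationError(ValidationError):
    """A signal is unrepresentable at every gain level of the encoder."""


class IntegrityError(SSXError):
    """Data on the wire or on disk is internally inconsistent."""


class DatagramFormatError(IntegrityError):
    """Base for wire-format parse failures."""


class BadMagicError(DatagramFormatError):
    """Serialized datagram does not start with the expected magic tag."""


class UnsupportedVersionError(DatagramFormatError):
    """Datagram header carries a version this codec does not speak."""


class TruncatedError(DatagramFormatError):
    """Buffer or file is shorter than its framing requires."""


class CapacityOverflowError(IntegrityError):
    """CSR compression would exceed the a-priori storage capacity."""

    def __init__(self, required: int, capacity: int):
        self.required = int(required)
        self.capacity = int(capacity)
        super().__init__(
            f"CSR capacity overflow: {self.required} values to store "
            f"but capacity is {self.capacity}; raise capacity to at least "
            f"{self.required}"
        )


class FileFormatError(IntegrityError):
    """An on-disk artifact is inconsistent with its sidecar or structure."""
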