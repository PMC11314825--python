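"""Core ECG container and error types shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ParameterError(ValueError):
    """A parameter violates its documented bounds."""


class LeadError(KeyError):
    """The requested lead does not exist in the record."""


class HeaderError(ValueError):
    """A record header is malformed or unreadable."""


class DegenerateSignalError(ValueError):
    """The signal carries no usable structure (e.g. constant trajectory)."""


@dataclass
class ECGSignal:
    """A uniformly sampled single-lead voltage series.

    Parameters
    ----------
    samples
        Voltage samples in millivolt.
    fs
        Sampling rate in Hz, > 0.
    record_id
        Provenance identifier (file stem, synthetic tag, ...).
    lead
        Lead name, e.g. ``"I"``.
    label
        Optional class label: 1 = pre-AF, 0 = non-AF.
    """

    samples: np.ndarray
    fs: float
    record_id: str = "unknown"
    lead: str = "I"
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must be finite")
        if self.label is not None and self.label not in (0, 1):
            raise ParameterError(f"label must be 0 or 1, got {self.label}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "ECGSignal":
        """Copy of this signal with new samples (and optionally new rate)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       fs=self.fs if fs is None else fs)
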