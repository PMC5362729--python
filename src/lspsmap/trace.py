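"""Uniformly sampled electrophysiology trace container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class InsufficientDataError(ValueError):
    """Raised when a measure has too few qualifying observations."""


class InfeasibleConstraintError(RuntimeError):
    """Raised when no stimulus ordering satisfies the separation constraint."""


class DegenerateMapError(ValueError):
    """Raised when a map has zero baseline-charge variance across spots."""


class DegenerateFitError(ValueError):
    """Raised for FI data that cannot constrain the model (e.g. all-zero rates)."""

    def __init__(self, message, fit=None):
        super().__init__(message)
        self.fit = fit


@dataclass
class Trace:
    """A uniformly sampled current (pA) or voltage (mV) signal.

    Parameters
    ----------
    samples : ndarray
        Signal values; must be finite.
    sample_interval : float
        Sampling interval in seconds.
    t0 : float
        Time of the first sample in seconds.  Map recordings place the
        light flash at t = 0, so baselines have negative times.
    units : str
        "pA" for currents, "mV" for voltages.
    """

    samples: np.ndarray
    sample_interval: float
    t0: float = 0.0
    units: str = "pA"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be positive")

    def __len__(self):
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.samples.size * self.sample_interval

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) * self.sample_interval

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in milliseconds."""
        return self.times * 1e3

    @property
    def t0_ms(self) -> float:
        return self.t0 * 1e3

    @property
    def t_end_ms(self) -> float:
        """Time just past the final sample, in ms."""
        return (self.t0 + self.duration) * 1e3

    def index_of_ms(self, t_ms: float) -> int:
        """Index of the sample at/after time ``t_ms`` (milliseconds)."""
        return int(np.ceil((t_ms * 1e-3 - self.t0) / self.sample_interval - 1e-9))

    def slice_ms(self, t_start_ms: float, t_end_ms: float) -> np.ndarray:
        """Samples in the half-open window [t_start_ms, t_end_ms)."""
        i0 = self.index_of_ms(t_start_ms)
        i1 = self.index_of_ms(t_end_ms)
        if i0 < 0 or i1 > self.samples.size or i1 <= i0:
            raise ValueError(
                f"window [{t_start_ms}, {t_end_ms}) ms outside trace "
                f"[{self.t0_ms:g}, {self.t_end_ms:g}) ms"
            )
        return self.samples[i0:i1]

    def with_samples(self, samples: np.ndarray) -> "Trace":
        """A copy of this trace carrying new sample values."""
        return replace(self, samples=np.asarray(samples, dtype=float))
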