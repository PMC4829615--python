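"""Frequency-band definitions for infra-slow oscillation analysis.

Resting-state BOLD fluctuations are conventionally partitioned into
infra-slow bands: slow-5 (0.01-0.027 Hz) and slow-4 (0.027-0.073 Hz)
carry most gray-matter signal and are the objects of band-limited fALFF.
On top of those this module defines the composite "resting" band
(slow-5 union slow-4), the low/high-frequency bands used by the spectral
robustness filter (LF 0.01-0.1 Hz vs HF 0.1 Hz-Nyquist), and the full
acquired range (0-Nyquist) that serves as the fALFF denominator.

All bands are half-open ``[lo, hi)`` except those whose upper edge is the
Nyquist frequency, which include it; a Fourier frequency at exactly
0.027 Hz therefore belongs to slow-4, not slow-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import UnsupportedSamplingError

__all__ = ["Band", "BandScheme", "make_band_scheme", "SLOW5", "SLOW4"]

# Canonical infra-slow band edges (Hz).
SLOW5 = (0.01, 0.027)
SLOW4 = (0.027, 0.073)
LF_EDGE = 0.1  # upper edge of the low-frequency robustness band


@dataclass(frozen=True)
class Band:
    """One named frequency interval in Hz.

    ``closed_upper`` marks bands that include their upper edge (only
    bands ending at Nyquist do).
    """

    label: str
    lo: float
    hi: float
    closed_upper: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi):
            raise ValueError(
                f"band {self.label!r}: need 0 <= lo < hi, got [{self.lo}, {self.hi})"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean membership of each frequency in this band."""
        freqs = np.asarray(freqs, dtype=float)
        if self.closed_upper:
            # tolerate floating representation of the Nyquist frequency
            upper = freqs <= self.hi * (1.0 + 1e-12)
        else:
            upper = freqs < self.hi
        return (freqs >= self.lo) & upper

    def contains(self, f: float) -> bool:
        return bool(self.mask(np.asarray([f]))[0])


@dataclass(frozen=True)
class BandScheme:
    """Ordered collection of named bands tied to one Nyquist frequency."""

    name: str
    nyquist: float
    bands: tuple[Band, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        labels = [b.label for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError("band labels must be unique")
        for b in self.bands:
            if b.hi > self.nyquist * (1.0 + 1e-12):
                raise ValueError(
                    f"band {b.label!r} upper edge {b.hi} exceeds Nyquist {self.nyquist}"
                )

    def __getitem__(self, label: str) -> Band:
        for b in self.bands:
            if b.label == label:
                return b
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(b.label == label for b in self.bands)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    def membership(self, f: float) -> list[str]:
        """Labels of every band containing frequency ``f``."""
        return [b.label for b in self.bands if b.contains(f)]


def make_band_scheme(nyquist: float, name: str = "infraslow") -> BandScheme:
    """Build the standard band scheme for a scan with the given Nyquist (Hz).

    Returns slow-5 [0.01, 0.027), slow-4 [0.027, 0.073), their union
    "resting" [0.01, 0.073), the robustness bands "lf" [0.01, 0.1) and
    "hf" [0.1, nyquist], and "full" [0, nyquist].

    Raises
    ------
    UnsupportedSamplingError
        If the Nyquist frequency does not cover slow-4 (<= 0.073 Hz); the
        slow-4 band would be truncated and band fALFF ill-defined.
    """
    if nyquist <= SLOW4[1]:
        raise UnsupportedSamplingError(
            f"Nyquist {nyquist} Hz <= {SLOW4[1]} Hz: slow-4 band not fully sampled"
        )
    bands = [
        Band("slow5", *SLOW5),
        Band("slow4", *SLOW4),
        Band("resting", SLOW5[0], SLOW4[1]),
        Band("full", 0.0, nyquist, closed_upper=True),
    ]
    if nyquist > LF_EDGE:
        bands.insert(2, Band("lf", SLOW5[0], LF_EDGE))
        bands.insert(3, Band("hf", LF_EDGE, nyquist, closed_upper=True))
    else:
        # slow bands fit but no high-frequency range exists; the
        # robustness filter then treats every component as narrow-band.
        bands.insert(2, Band("lf", SLOW5[0], nyquist, closed_upper=True))
    return BandScheme(name=name, nyquist=float(nyquist), bands=tuple(bands))
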