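"""Informational spectrum of an EIIP numeric series.

The discrete Fourier transform used here follows the ISM convention:

    X(n) = sum_{m=1..N} x(m) * exp(-i 2 pi n (m-1) / N),   n = 1 .. floor(N/2)

and the informational spectrum is the energy density

    S(n) = X(n) X*(n) = |X(n)|^2

over the dimensionless frequency grid f_n = n/N.  Positions are taken as
equidistant with unit spacing (d = 1), so the largest frequency is
1/(2d) = 0.5, attained exactly when N is even.  The DC bin (n = 0) is
excluded: the spectrum is therefore invariant to adding a constant to the
series, and mean-centering is a no-op.

No windowing, zero-padding or normalisation is applied; amplitudes are raw
squared moduli of the Fourier coefficients.  Internally the coefficients
come from a real FFT, whose one-sided output coincides with the direct sum
above.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class InformationalSpectrum:
    """Energy-density spectrum of one numeric series.

    Attributes
    ----------
    frequencies
        Grid f_n = n/N for n = 1..floor(N/2), strictly increasing.
    amplitudes
        Non-negative energies S(n) = |X(n)|^2, aligned with ``frequencies``.
    source_length
        Length N of the encoded sequence the spectrum came from.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        if len(self.frequencies) != len(self.amplitudes):
            raise InvalidInputError("frequency and amplitude grids differ in length")
        if len(self.frequencies) != self.source_length // 2:
            raise InvalidInputError(
                "spectrum must have floor(N/2) bins for a series of length N"
            )

    @property
    def n_bins(self) -> int:
        return len(self.frequencies)

    def amplitude_at(self, index: int) -> float:
        """S(n) for a 1-based frequency index n."""
        if not 1 <= index <= self.n_bins:
            raise InvalidInputError(
                f"frequency index {index} outside [1, {self.n_bins}]"
            )
        return float(self.amplitudes[index - 1])

    def to_file(self, path: str | Path, sep: str = "\t") -> None:
        """Write the spectrum as two-column delimited text (frequency, amplitude)."""
        lines = ["frequency" + sep + "amplitude"]
        for f, a in zip(self.frequencies, self.amplitudes):
            lines.append(f"{f:.6f}{sep}{a:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


def fourier_coefficients(series: np.ndarray) -> np.ndarray:
    """Discrete Fourier coefficients X(n) for n = 1..floor(N/2).

    The DC bin is excluded.  Raises :class:`InvalidInputError` for series
    shorter than 2 (a single point has no nonzero frequency bin).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError("series must be one-dimensional")
    n = x.size
    if n < 2:
        raise InvalidInputError(f"series length {n} < 2: no spectrum is defined")
    # rfft returns bins 0..floor(N/2) with the same sign convention as the
    # direct sum over m-1 = 0..N-1.
    return np.fft.rfft(x)[1 : n // 2 + 1]


def informational_spectrum(series: np.ndarray) -> InformationalSpectrum:
    """Energy-density spectrum S(n) = |X(n)|^2 on the grid f_n = n/N."""
    x = np.asarray(series, dtype=float)
    coeffs = fourier_coefficients(x)
    n = x.size
    freqs = np.arange(1, n // 2 + 1, dtype=float) / n
    amps = np.abs(coeffs) ** 2
    return InformationalSpectrum(frequencies=freqs, amplitudes=amps, source_length=n)
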