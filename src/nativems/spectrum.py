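"""The :class:`Spectrum` container.

A native mass spectrum is carried throughout the package as a pair of
aligned arrays: m/z values in Thomson (Da per elementary charge) and
intensities in arbitrary units.  After normalization the intensities are on
a percent-of-base-peak scale (tallest peak = 100), the convention vendor
software uses for relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

__all__ = ["Spectrum"]

#: Normalization target: base peak is scaled to this value.
BASE_PEAK = 100.0


@dataclass(frozen=True)
class Spectrum:
    """An m/z / intensity trace.

    Parameters
    ----------
    mz
        Strictly increasing m/z values (Thomson).
    intensity
        Intensities aligned with ``mz``; finite, arbitrary units.

    Both arrays are copied and frozen on construction so that spectra can be
    shared between a session's raw record and derived working copies without
    aliasing surprises.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or inten.ndim != 1:
            raise ParameterError("mz and intensity must be one-dimensional")
        if mz.size == 0 or mz.size != inten.size:
            raise ParameterError(
                f"mz and intensity must have identical nonzero length "
                f"(got {mz.size} and {inten.size})"
            )
        if not (np.all(np.isfinite(mz)) and np.all(np.isfinite(inten))):
            raise ParameterError("mz and intensity must be finite")
        if np.any(np.diff(mz) <= 0):
            raise ParameterError("mz must be strictly increasing")
        mz.setflags(write=False)
        inten.setflags(write=False)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def mz_range(self) -> tuple[float, float]:
        return float(self.mz[0]), float(self.mz[-1])

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        """Return a new spectrum on the same m/z grid."""
        return Spectrum(self.mz, np.asarray(intensity, dtype=float))

    def normalized(self, target: float = BASE_PEAK) -> "Spectrum":
        """Scale intensities so the base peak equals ``target`` (default 100).

        A spectrum whose maximum intensity is not positive is returned
        unchanged (there is nothing to scale by).
        """
        peak = float(np.max(self.intensity))
        if peak <= 0:
            return self
        return self.with_intensity(self.intensity * (target / peak))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return np.array_equal(self.mz, other.mz) and np.array_equal(
            self.intensity, other.intensity
        )

    def allclose(self, other: "Spectrum", rtol: float = 1e-12, atol: float = 0.0) -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.mz, other.mz, rtol=rtol, atol=atol)
            and np.allclose(self.intensity, other.intensity, rtol=rtol, atol=atol)
        )

    def plot(self, ax=None, **kwargs):
        """Plot the trace on a matplotlib axis (created if not given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.mz, self.intensity, **kwargs)
        ax.set_xlabel("m/z (Th)")
        ax.set_ylabel("intensity")
        return ax
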