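"""Spectrum preprocessing: smoothing, background subtraction, intensity filter.

The four operations mirror the processing palette of standard native-MS
software (UniDec and kin): Gaussian smoothing (repeatable), three background
subtraction modes (constant, linear between the endpoints, curved), and a
minimum-intensity filter.  All operations preserve the m/z grid and array
length, and all subtractions clamp at zero so intensities stay non-negative.

Widths (``sigma``, ``window``) are expressed in numbers of data points, not
Thomson, because exported CSVs need not be uniformly gridded.

Every public operation has a matching :class:`ProcessingStep` record so a
session's processing log can be replayed bit-for-bit (see
:func:`apply_step` / :func:`apply_steps`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError
from .spectrum import Spectrum

__all__ = [
    "ProcessingStep",
    "gaussian_smooth",
    "subtract_constant",
    "subtract_linear",
    "subtract_curved",
    "apply_min_intensity",
    "normalize",
    "apply_step",
    "apply_steps",
]

# Kernel contract shared by gaussian_smooth and subtract_curved's baseline
# smoothing: unit-area Gaussian truncated at 4 sigma, nearest-value edges.
_TRUNCATE = 4.0


@dataclass(frozen=True)
class ProcessingStep:
    """One recorded operation of the processing log.

    ``name`` is from the closed set {smooth, subtract_constant,
    subtract_linear, subtract_curved, min_intensity, normalize}; ``params``
    holds exactly that operation's parameters.
    """

    name: str
    params: Mapping[str, Any] = field(default_factory=dict)

    _ALLOWED = frozenset(
        {
            "smooth",
            "subtract_constant",
            "subtract_linear",
            "subtract_curved",
            "min_intensity",
            "normalize",
        }
    )

    def __post_init__(self) -> None:
        if self.name not in self._ALLOWED:
            raise ParameterError(
                f"unknown processing step {self.name!r}; "
                f"expected one of {sorted(self._ALLOWED)}"
            )
        object.__setattr__(self, "params", dict(self.params))

    def to_dict(self) -> dict[str, Any]:
        return {"name": self.name, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ProcessingStep":
        return cls(name=d["name"], params=dict(d.get("params", {})))


def gaussian_smooth(s: Spectrum, sigma: float, repeats: int = 1) -> Spectrum:
    """Convolve intensities with a unit-area Gaussian, ``repeats`` times.

    ``sigma`` is the kernel standard deviation in data points.  The kernel
    is truncated at 4 sigma and edges are handled by nearest-value
    extension, so a constant spectrum is invariant and total intensity is
    conserved for signal at least 4 sigma from the edges.
    """
    if not sigma > 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    if int(repeats) != repeats or repeats < 1:
        raise ParameterError(f"repeats must be a positive integer, got {repeats}")
    out = np.asarray(s.intensity, dtype=float)
    for _ in range(int(repeats)):
        out = ndimage.gaussian_filter1d(out, sigma=float(sigma), mode="nearest",
                                        truncate=_TRUNCATE)
    return s.with_intensity(out)


def subtract_constant(s: Spectrum, value: float) -> Spectrum:
    """Subtract a fixed intensity value, clamping at zero."""
    if value < 0:
        raise ParameterError(f"subtraction value must be >= 0, got {value}")
    return s.with_intensity(np.maximum(s.intensity - float(value), 0.0))


def subtract_linear(s: Spectrum) -> Spectrum:
    """Subtract the line through the first and last (m/z, intensity) points.

    The endpoints become exactly zero; everything clamps at zero.
    """
    if len(s) < 2:
        raise ParameterError("linear subtraction needs a spectrum of length >= 2")
    x0, x1 = s.mz[0], s.mz[-1]
    y0, y1 = s.intensity[0], s.intensity[-1]
    baseline = y0 + (s.mz - x0) * ((y1 - y0) / (x1 - x0))
    out = np.maximum(s.intensity - baseline, 0.0)
    # the endpoints are on the line by construction; pin them against
    # floating-point residue so the contract "exactly zero" holds
    out[0] = 0.0
    out[-1] = 0.0
    return s.with_intensity(out)


def subtract_curved(s: Spectrum, window: int) -> Spectrum:
    """Subtract a curved baseline: smoothed rolling minimum of the intensities.

    The baseline is the rolling minimum over a centred window of ``window``
    data points, Gaussian-smoothed with sigma = window / 2 under the same
    kernel contract as :func:`gaussian_smooth`.  Features much narrower than
    the window survive nearly untouched; structure much broader than the
    window is treated as background.
    """
    if int(window) != window or window < 3 or window >= len(s):
        raise ParameterError(
            f"window must be an integer in [3, {len(s) - 1}], got {window}"
        )
    rolled = ndimage.minimum_filter1d(s.intensity, size=int(window), mode="nearest")
    baseline = ndimage.gaussian_filter1d(rolled, sigma=window / 2.0, mode="nearest",
                                         truncate=_TRUNCATE)
    return s.with_intensity(np.maximum(s.intensity - baseline, 0.0))


def apply_min_intensity(s: Spectrum, threshold: float) -> Spectrum:
    """Zero intensities strictly below ``threshold``; grid unchanged.

    Points are zeroed, not removed, so array alignment and session replay
    are preserved.  Points exactly at the threshold are kept.
    """
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    out = np.where(s.intensity < float(threshold), 0.0, s.intensity)
    return s.with_intensity(out)


def normalize(s: Spectrum) -> Spectrum:
    """Scale so the base peak equals 100 (relative-abundance percent)."""
    return s.normalized()


_DISPATCH = {
    "smooth": lambda s, p: gaussian_smooth(s, sigma=p["sigma"],
                                           repeats=int(p.get("repeats", 1))),
    "subtract_constant": lambda s, p: subtract_constant(s, value=p["value"]),
    "subtract_linear": lambda s, p: subtract_linear(s),
    "subtract_curved": lambda s, p: subtract_curved(s, window=int(p["window"])),
    "min_intensity": lambda s, p: apply_min_intensity(s, threshold=p["threshold"]),
    "normalize": lambda s, p: normalize(s),
}


def apply_step(s: Spectrum, step: ProcessingStep) -> Spectrum:
    """Apply one recorded processing step."""
    return _DISPATCH[step.name](s, step.params)


def apply_steps(s: Spectrum, steps: Iterable[ProcessingStep]) -> Spectrum:
    """Replay a processing log in order; deterministic and bit-reproducible."""
    for step in steps:
        s = apply_step(s, step)
    return s
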