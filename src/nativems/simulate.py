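"""Synthetic native-MS spectrum generator with exact ground truth.

Emulates the first-order physics of a native electrospray spectrum: each
species of known mass carries a bell-shaped (Gaussian) envelope of
consecutive charge states, each charge state contributes a Gaussian peak at
``(mass + z * adduct) / z`` with a stated FWHM, and the whole trace sits on
an optional baseline with optional additive Gaussian noise.  The generator
returns both the spectrum and a :class:`SimulatedTruth` record whose peak
positions are computed from the same electrospray relation the assignment
module inverts — so every downstream module can be tested against exact
ground truth without any experimental data.

Deliberately not modelled: physical ESI charging, isotope distributions,
detector saturation, adduct heterogeneity.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence, Union

import numpy as np

from .assign import PROTON_MASS, mz_from_mass
from .exceptions import ParameterError
from .spectrum import Spectrum

__all__ = ["SpeciesSpec", "SimulatedTruth", "simulate_spectrum", "ClippedPeaksWarning"]

#: Charge states with envelope weight below this are dropped from the truth
#: table (and the spectrum), bounding the peak table.
ENVELOPE_CUTOFF = 1e-4

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class ClippedPeaksWarning(UserWarning):
    """Some above-cutoff peaks fall outside the simulated m/z range."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One simulated species.

    ``charge_center`` / ``charge_spread`` parameterize the Gaussian charge
    envelope: charge z gets weight exp(-(z - center)^2 / (2 spread^2)).
    ``abundance`` scales the species relative to others; ``peak_fwhm`` is
    the full width at half maximum of each peak, in Thomson.
    """

    name: str
    mass: float
    charge_center: float
    charge_spread: float
    abundance: float = 1.0
    peak_fwhm: float = 2.0

    def __post_init__(self) -> None:
        if not (self.mass > 0 and self.charge_center >= 1 and self.charge_spread > 0
                and self.abundance > 0 and self.peak_fwhm > 0):
            raise ParameterError(f"invalid species spec {self!r}")

    def envelope(self) -> list[tuple[int, float]]:
        """(charge, weight) for every charge with weight above the cutoff."""
        half = self.charge_spread * math.sqrt(-2.0 * math.log(ENVELOPE_CUTOFF))
        z_lo = max(1, math.ceil(self.charge_center - half))
        z_hi = math.floor(self.charge_center + half)
        out = []
        for z in range(z_lo, z_hi + 1):
            w = math.exp(-((z - self.charge_center) ** 2)
                         / (2.0 * self.charge_spread ** 2))
            if w > ENVELOPE_CUTOFF:
                out.append((z, w))
        return out

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name, "mass": self.mass,
            "charge_center": self.charge_center,
            "charge_spread": self.charge_spread,
            "abundance": self.abundance, "peak_fwhm": self.peak_fwhm,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SpeciesSpec":
        return cls(**{k: d[k] for k in
                      ("name", "mass", "charge_center", "charge_spread")}
                   | {k: d[k] for k in ("abundance", "peak_fwhm") if k in d})


@dataclass(frozen=True)
class SimulatedTruth:
    """Exact ground truth of a simulated spectrum.

    ``peak_table[name]`` lists (charge, m/z, relative height) per species;
    m/z values satisfy the electrospray relation exactly.
    """

    species: tuple[SpeciesSpec, ...]
    peak_table: Mapping[str, list[tuple[int, float, float]]]
    baseline_params: Mapping[str, Any]
    noise_sigma: float
    seed: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "species": [sp.to_dict() for sp in self.species],
            "peak_table": {
                name: [[z, mz, h] for z, mz, h in rows]
                for name, rows in self.peak_table.items()
            },
            "baseline_params": dict(self.baseline_params),
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    def save_json(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _parse_baseline(baseline: Union[str, None]) -> tuple[str, float]:
    if baseline is None or baseline == "none":
        return "none", 0.0
    if isinstance(baseline, str) and ":" in baseline:
        kind, _, val = baseline.partition(":")
        if kind in ("linear", "curved"):
            return kind, float(val)
    raise ParameterError(
        f"baseline must be 'none', 'linear:SLOPE' or 'curved:AMPLITUDE', "
        f"got {baseline!r}"
    )


def simulate_spectrum(
    species: Sequence[SpeciesSpec],
    mz_range: tuple[float, float],
    n_points: int = 2000,
    baseline: Union[str, None] = "none",
    noise_sigma: float = 0.0,
    seed: int = 0,
    adduct_mass: float = PROTON_MASS,
) -> tuple[Spectrum, SimulatedTruth]:
    """Simulate a native-MS spectrum on a uniform m/z grid.

    Parameters
    ----------
    species
        One or more :class:`SpeciesSpec`.
    mz_range
        (lo, hi) of the uniform grid, Thomson.
    n_points
        Grid size (>= 100).
    baseline
        ``"none"``, ``"linear:SLOPE"`` (percent per Thomson, anchored at
        zero on the left edge) or ``"curved:AMPLITUDE"`` (a broad Gaussian
        hump centred mid-range, width = range/4, amplitude in percent).
    noise_sigma
        Standard deviation of additive Gaussian intensity noise, in percent
        of the clean signal's base peak (the clean signal is scaled to
        base peak = 100 before baseline and noise are added, so baseline
        and noise parameters are in percent units).
    seed
        Seeds the noise generator; identical seeds give bitwise-identical
        spectra.

    Returns the normalized spectrum and the exact truth record.  Peaks with
    envelope weight above the cutoff that fall outside ``mz_range`` trigger
    a :class:`ClippedPeaksWarning` naming them.
    """
    lo, hi = mz_range
    if not (hi > lo):
        raise ParameterError(f"invalid mz_range {mz_range}")
    if n_points < 100:
        raise ParameterError(f"n_points must be >= 100, got {n_points}")
    if not species:
        raise ParameterError("species list is empty")
    if noise_sigma < 0:
        raise ParameterError(f"noise_sigma must be >= 0, got {noise_sigma}")

    grid = np.linspace(lo, hi, int(n_points))
    signal = np.zeros_like(grid)
    peak_table: dict[str, list[tuple[int, float, float]]] = {}
    clipped: list[str] = []

    for sp in species:
        rows: list[tuple[int, float, float]] = []
        sig = sp.peak_fwhm * _FWHM_TO_SIGMA
        for z, w in sp.envelope():
            center = mz_from_mass(sp.mass, z, adduct_mass)
            height = sp.abundance * w
            rows.append((z, center, height))
            if not (lo <= center <= hi):
                clipped.append(f"{sp.name} z={z} at m/z {center:.2f}")
                continue
            signal += height * np.exp(-((grid - center) ** 2) / (2.0 * sig ** 2))
        peak_table[sp.name] = rows

    if clipped:
        warnings.warn(
            "peaks outside mz_range were clipped: " + "; ".join(clipped),
            ClippedPeaksWarning,
            stacklevel=2,
        )

    # put the clean signal on the percent-of-base-peak scale first, so
    # baseline and noise parameters are in interpretable units (percent)
    peak = float(signal.max())
    if peak > 0:
        signal = signal * (100.0 / peak)

    kind, val = _parse_baseline(baseline)
    if kind == "linear":
        signal = signal + val * (grid - lo)
    elif kind == "curved":
        center = 0.5 * (lo + hi)
        width = (hi - lo) / 4.0
        signal = signal + val * np.exp(-((grid - center) ** 2) / (2.0 * width ** 2))

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma, size=signal.size)

    spectrum = Spectrum(grid, signal).normalized()
    truth = SimulatedTruth(
        species=tuple(species),
        peak_table=peak_table,
        baseline_params={"kind": kind, "value": val},
        noise_sigma=float(noise_sigma),
        seed=int(seed),
    )
    return spectrum, truth
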