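"""Charge-series assignment for native mass spectra.

In electrospray ionization a species of neutral mass :math:`M` carrying
:math:`z` charge-imparting adducts (protons in positive mode) appears at

.. math::  m/z = (M + z\\,m_a) / z

with adduct mass :math:`m_a` (1.007276 Da for a proton).  One folded
species gives a *series* of peaks at consecutive charges.  The assignment
problem — given a handful of picked peaks, which consecutive charges do
they carry? — is solved here by the MacSED variance-minimization algorithm:
every candidate consecutive charge vector is tried, each peak's m/z is
deconvolved to a neutral mass under that vector, and the vector whose
implied masses are most self-consistent (minimal variance) wins.  The mean
of the winning masses is the reported mass; their sample standard deviation
is its uncertainty.

The estimator is exposed statsmodels-style: build a
:class:`ChargeSeriesModel` from picked peaks, call :meth:`~ChargeSeriesModel.fit`,
and get a :class:`ChargeSeriesResults` carrying the estimate, its
uncertainty, the full variance profile over candidate base charges, and a
``summary()`` table.  :func:`macsed_assign` is the one-call functional form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .exceptions import AssignmentError, ParameterError, WindowError
from .spectrum import Spectrum

__all__ = [
    "PROTON_MASS",
    "Peak",
    "ChargeSeries",
    "ChargeSeriesModel",
    "ChargeSeriesResults",
    "mz_from_mass",
    "pick_peaks",
    "macsed_assign",
    "mass_finder",
    "predict_adjacent",
]

#: Average mass of a proton in Da — the default charge carrier
#: (positive ion mode).  Exposed as a parameter everywhere for negative
#: mode or alternative adducts.  The electron mass is not subtracted.
PROTON_MASS = 1.007276


def mz_from_mass(mass: float, z: int, adduct_mass: float = PROTON_MASS) -> float:
    """m/z of a species of neutral ``mass`` carrying ``z`` adducts.

    ``(mass + z * adduct_mass) / z`` — the standard electrospray relation.
    """
    if mass <= 0:
        raise ParameterError(f"mass must be > 0, got {mass}")
    if int(z) != z or z < 1:
        raise ParameterError(f"charge must be a positive integer, got {z}")
    return (mass + z * adduct_mass) / z


@dataclass(frozen=True)
class Peak:
    """A picked peak: the apex sample inside a user-chosen m/z window."""

    mz: float
    intensity: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (lo <= self.mz <= hi):
            raise ParameterError(
                f"peak m/z {self.mz} outside its window [{lo}, {hi}]"
            )
        if not self.intensity > 0:
            raise ParameterError(f"peak intensity must be > 0, got {self.intensity}")


@dataclass(frozen=True)
class ChargeSeries:
    """An assigned charge-state series.

    ``peaks`` are sorted descending by m/z and aligned with ``charges``,
    which are consecutive ascending positive integers (no missing charge
    states).  ``mass`` is the mean of the per-peak deconvolved masses and
    ``uncertainty`` their sample (k-1) standard deviation.
    """

    name: str
    peaks: tuple[Peak, ...]
    charges: tuple[int, ...]
    mass: float
    uncertainty: float
    adduct_mass: float = PROTON_MASS

    def __post_init__(self) -> None:
        peaks = tuple(self.peaks)
        charges = tuple(int(z) for z in self.charges)
        if len(peaks) != len(charges) or len(peaks) < 2:
            raise ParameterError("a series needs >= 2 peaks aligned with charges")
        if any(b - a != 1 for a, b in zip(charges, charges[1:])):
            raise ParameterError("charges must be consecutive ascending integers")
        if charges[0] < 1:
            raise ParameterError("charges must be >= 1")
        if any(p1.mz <= p2.mz for p1, p2 in zip(peaks, peaks[1:])):
            raise ParameterError("peaks must be sorted strictly descending by m/z")
        if not self.mass > 0 or self.uncertainty < 0:
            raise ParameterError("mass must be > 0 and uncertainty >= 0")
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(self, "charges", charges)

    @property
    def charge_min(self) -> int:
        return self.charges[0]

    @property
    def charge_max(self) -> int:
        return self.charges[-1]

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "peaks": [
                {"mz": p.mz, "intensity": p.intensity, "window": list(p.window)}
                for p in self.peaks
            ],
            "charges": list(self.charges),
            "mass": self.mass,
            "uncertainty": self.uncertainty,
            "adduct_mass": self.adduct_mass,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ChargeSeries":
        return cls(
            name=d["name"],
            peaks=tuple(
                Peak(mz=p["mz"], intensity=p["intensity"], window=tuple(p["window"]))
                for p in d["peaks"]
            ),
            charges=tuple(d["charges"]),
            mass=d["mass"],
            uncertainty=d["uncertainty"],
            adduct_mass=d.get("adduct_mass", PROTON_MASS),
        )


def pick_peaks(s: Spectrum, windows: Sequence[tuple[float, float]]) -> list[Peak]:
    """One apex peak per m/z window.

    Each window is a closed interval on the m/z axis (the scripted
    counterpart of a cursor selection).  The sample of maximum intensity
    inside the window becomes the peak; ties break to the lowest m/z.
    Windows in which every sample has zero intensity yield no peak and are
    silently excluded.  A window that does not contain any sample raises
    :class:`~nativems.exceptions.WindowError`.
    """
    if not windows:
        raise ParameterError("at least one window is required")
    peaks: list[Peak] = []
    for lo, hi in windows:
        if hi < lo:
            raise WindowError(f"window ({lo}, {hi}) has hi < lo", window=(lo, hi))
        idx = np.nonzero((s.mz >= lo) & (s.mz <= hi))[0]
        if idx.size == 0:
            raise WindowError(
                f"window ({lo}, {hi}) contains no samples of the spectrum "
                f"(m/z range {s.mz_range[0]:.6g}-{s.mz_range[1]:.6g})",
                window=(lo, hi),
            )
        inten = s.intensity[idx]
        if np.max(inten) <= 0:
            continue  # empty window: nothing above zero to pick
        apex = idx[int(np.argmax(inten))]  # argmax -> first max -> lowest m/z
        peaks.append(Peak(mz=float(s.mz[apex]), intensity=float(s.intensity[apex]),
                          window=(float(lo), float(hi))))
    return peaks


class ChargeSeriesModel:
    """MacSED charge-series estimator over a set of picked peaks.

    Parameters
    ----------
    peaks
        Two or more :class:`Peak` with distinct m/z (order irrelevant;
        they are sorted descending by m/z internally).
    z_max
        Largest candidate charge considered (default 500, which covers
        MDa-scale assemblies; the variance at implausibly high charge
        grows without bound, so the cap mainly bounds runtime).
    adduct_mass
        Charge-carrier mass in Da, proton by default.

    The model assumes the peaks come from one species at consecutive
    charge states with no gaps.  ``fit()`` scans every admissible base
    charge (the charge of the highest-m/z peak), deconvolves each peak to
    a neutral mass under that assignment, and picks the base charge whose
    mass vector has minimal variance, smallest base charge winning ties.
    """

    def __init__(self, peaks: Iterable[Peak], z_max: int = 500,
                 adduct_mass: float = PROTON_MASS):
        peaks = sorted(peaks, key=lambda p: -p.mz)
        if len(peaks) < 2:
            raise AssignmentError("need at least 2 peaks to assign a series")
        mzs = np.array([p.mz for p in peaks], dtype=float)
        if np.unique(mzs).size != mzs.size:
            raise AssignmentError("peaks must have distinct m/z values")
        if int(z_max) != z_max or z_max < 1:
            raise ParameterError(f"z_max must be a positive integer, got {z_max}")
        if len(peaks) - 1 >= z_max:
            raise AssignmentError(
                f"{len(peaks)} peaks cannot carry consecutive charges within "
                f"1..{z_max}"
            )
        self.peaks: tuple[Peak, ...] = tuple(peaks)
        self.mz: np.ndarray = mzs
        self.z_max = int(z_max)
        self.adduct_mass = float(adduct_mass)

    @property
    def nobs(self) -> int:
        return len(self.peaks)

    def fit(self, name: str = "series") -> "ChargeSeriesResults":
        """Run the variance-minimization scan and return the results."""
        k = self.nobs
        # candidate base charges: charge of the highest-m/z (lowest-charge) peak
        z0 = np.arange(1, self.z_max - k + 2)                    # (n_candidates,)
        charges = z0[:, None] + np.arange(k)[None, :]            # (n_cand, k)
        masses = self.mz[None, :] * charges - charges * self.adduct_mass
        variances = np.var(masses, axis=1, ddof=1)
        best = int(np.argmin(variances))  # argmin -> first minimum -> smallest z0
        mass_vec = masses[best]
        mass = float(np.mean(mass_vec))
        uncertainty = float(np.std(mass_vec, ddof=1))
        series = ChargeSeries(
            name=name,
            peaks=self.peaks,
            charges=tuple(int(z) for z in charges[best]),
            mass=mass,
            uncertainty=uncertainty,
            adduct_mass=self.adduct_mass,
        )
        return ChargeSeriesResults(
            model=self,
            series=series,
            base_charges=z0,
            variance_profile=variances,
            mass_vector=mass_vec,
        )


@dataclass(frozen=True)
class ChargeSeriesResults:
    """Fit results: the assigned series plus diagnostics.

    ``variance_profile[i]`` is the sample variance (Da^2) of the deconvolved
    mass vector under base charge ``base_charges[i]``; the selected base
    charge is its argmin.  ``mass_vector`` holds the per-peak masses of the
    winning assignment (their mean and sample sd are the reported mass and
    uncertainty).
    """

    model: ChargeSeriesModel
    series: ChargeSeries
    base_charges: np.ndarray
    variance_profile: np.ndarray
    mass_vector: np.ndarray

    @property
    def mass(self) -> float:
        return self.series.mass

    @property
    def uncertainty(self) -> float:
        return self.series.uncertainty

    @property
    def charges(self) -> tuple[int, ...]:
        return self.series.charges

    def predict(self, z: int | Sequence[int]) -> np.ndarray:
        """Predicted m/z of this species at charge(s) ``z``."""
        zs = np.atleast_1d(np.asarray(z, dtype=int))
        return np.array([mz_from_mass(self.mass, int(c), self.series.adduct_mass)
                         for c in zs])

    def predict_adjacent(self, n: int = 1) -> list[tuple[int, float]]:
        """Neighbouring charge states (see :func:`predict_adjacent`)."""
        return predict_adjacent(self.series, n=n)

    def summary(self) -> str:
        """Plain-text summary table in the style of statistical model fits."""
        s = self.series
        lines = [
            "MacSED charge-series assignment",
            "=" * 47,
            f"{'peaks':<24}{len(s.peaks):>23}",
            f"{'charges':<24}{f'{s.charge_min}..{s.charge_max}':>23}",
            f"{'adduct mass (Da)':<24}{s.adduct_mass:>23.6f}",
            f"{'mass (Da)':<24}{s.mass:>23.4f}",
            f"{'uncertainty, sd (Da)':<24}{s.uncertainty:>23.4f}",
            f"{'min variance (Da^2)':<24}{np.min(self.variance_profile):>23.6g}",
            "-" * 47,
            f"{'charge':>8}{'m/z (Th)':>16}{'mass (Da)':>16}",
        ]
        for z, p, m in zip(s.charges, s.peaks, self.mass_vector):
            lines.append(f"{z:>8d}{p.mz:>16.4f}{m:>16.4f}")
        lines.append("=" * 47)
        return "\n".join(lines)

    def plot_variance_profile(self, ax=None, **kwargs):
        """Plot variance vs candidate base charge (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.base_charges, self.variance_profile, **kwargs)
        ax.axvline(self.series.charge_min, color="r", lw=0.8)
        ax.set_xlabel("candidate base charge $z_0$")
        ax.set_ylabel("mass variance (Da$^2$)")
        return ax


def macsed_assign(peaks: Iterable[Peak], z_max: int = 500,
                  adduct_mass: float = PROTON_MASS, name: str = "series") -> ChargeSeries:
    """Assign consecutive charges to peaks by MacSED variance minimization.

    Functional one-call form of :class:`ChargeSeriesModel` + ``fit()``;
    returns the :class:`ChargeSeries` only.
    """
    return ChargeSeriesModel(peaks, z_max=z_max, adduct_mass=adduct_mass).fit(name).series


def mass_finder(mass: float, z_lo: int, z_hi: int,
                adduct_mass: float = PROTON_MASS) -> list[tuple[int, float]]:
    """Where would a complex of ``mass`` appear? (charge, m/z) for z_lo..z_hi.

    Ascending charge, hence descending m/z — for highlighting the m/z
    regions in which a species of known mass is expected.
    """
    if int(z_lo) != z_lo or int(z_hi) != z_hi or z_lo < 1 or z_hi < z_lo:
        raise ParameterError(
            f"need 1 <= z_lo <= z_hi, got z_lo={z_lo}, z_hi={z_hi}"
        )
    return [(z, mz_from_mass(mass, z, adduct_mass))
            for z in range(int(z_lo), int(z_hi) + 1)]


def predict_adjacent(series: ChargeSeries, n: int = 1) -> list[tuple[int, float]]:
    """Predicted (charge, m/z) for the ``n`` charge states on each side of a series.

    Charges below 1 are dropped; output sorted ascending by charge.  Used
    to disentangle overlapping series: if the spectrum shows intensity at
    these positions, the series likely extends there.
    """
    if int(n) != n or n < 1:
        raise ParameterError(f"n must be a positive integer, got {n}")
    lo, hi = series.charge_min, series.charge_max
    zs = [z for z in range(lo - int(n), lo) if z >= 1]
    zs += list(range(hi + 1, hi + int(n) + 1))
    return [(z, mz_from_mass(series.mass, z, series.adduct_mass)) for z in zs]
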