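"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (plain Python
loops) used to cross-check the vectorized / pruned library code; they must
stay independent of the implementation paths they verify.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from nativems import Peak, SpeciesSpec, Spectrum, simulate_spectrum
from nativems.assign import PROTON_MASS


# ------------------------------------------------------------- oracles

def brute_force_base_charge(mz_desc, z_max=500, adduct=PROTON_MASS):
    """Exhaustive variance scan over every candidate base charge.

    Returns (best_z0, masses_at_best).  Plain loops, first minimum wins —
    the independent reference for the vectorized MacSED scan.
    """
    k = len(mz_desc)
    best_z0, best_var, best_masses = None, None, None
    for z0 in range(1, z_max - k + 2):
        masses = [mz * (z0 + i) - (z0 + i) * adduct
                  for i, mz in enumerate(mz_desc)]
        mean = sum(masses) / k
        var = sum((m - mean) ** 2 for m in masses) / (k - 1)
        if best_var is None or var < best_var:
            best_z0, best_var, best_masses = z0, var, masses
    return best_z0, best_masses


def brute_force_stoichiometries(entries, target, tolerance):
    """Full nested-product enumeration (no pruning) of matching count vectors.

    ``entries`` is a list of (name, mass, max_copies).  Returns a set of
    frozensets of (name, count) pairs for order-free comparison.
    """
    names = [e[0] for e in entries]
    ranges = [range(e[2] + 1) for e in entries]
    solutions = set()
    for combo in itertools.product(*ranges):
        if not any(combo):
            continue
        total = sum(c * e[1] for c, e in zip(combo, entries))
        if abs(total - target) <= tolerance:
            solutions.add(frozenset(zip(names, combo)))
    return solutions


def series_peaks(mass, charges, adduct=PROTON_MASS, intensity=50.0):
    """Synthetic peaks placed exactly on the electrospray relation."""
    peaks = []
    for z in charges:
        mz = (mass + z * adduct) / z
        peaks.append(Peak(mz=mz, intensity=intensity, window=(mz - 1, mz + 1)))
    return peaks


# ------------------------------------------------------------ fixtures

@pytest.fixture
def flat_spectrum():
    return Spectrum(np.linspace(1000.0, 2000.0, 101), np.full(101, 5.0))


@pytest.fixture
def small_spectrum():
    return Spectrum(np.array([1000.0, 1001.0, 1002.0]),
                    np.array([25.0, 50.0, 100.0]))


@pytest.fixture
def tenk_spectrum():
    """Noiseless single species, mass 10 kDa, charges around 10."""
    species = [SpeciesSpec("tenk", mass=10000.0, charge_center=10.0,
                           charge_spread=1.0, abundance=1.0, peak_fwhm=1.0)]
    spectrum, truth = simulate_spectrum(species, mz_range=(700.0, 1700.0),
                                        n_points=10001, seed=11)
    return spectrum, truth
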