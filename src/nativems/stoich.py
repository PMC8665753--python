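"""Complex stoichiometry: match a measured mass to integer subunit combinations.

Given a table of known subunit average masses (from sequence databases, gels
or proteomics) and a deconvolved complex mass, enumerate every bounded
integer copy-number vector whose total mass falls within a tolerance of the
target.  This is a bounded subset-sum over real masses; explicit per-subunit
copy bounds keep the enumeration exact and finite, and branch-and-bound
pruning (a partial sum already above target + tolerance can never recover)
keeps it fast without changing the result set.

Masses are treated as average masses, the convention in native MS of large
complexes.  Tolerance is absolute in Da; a ppm convenience conversion is
provided via :func:`ppm_to_da`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence

from .assign import ChargeSeries
from .exceptions import ComplexityError, ParameterError

__all__ = [
    "Subunit",
    "SubunitTable",
    "StoichiometrySolution",
    "enumerate_stoichiometries",
    "score_series_against_subunits",
    "ppm_to_da",
]

#: Search-space guard: product of (max_copies + 1) over subunits must not
#: exceed this; beyond it the caller is asked to tighten max_copies.
MAX_SEARCH_NODES = 100_000_000


def ppm_to_da(ppm: float, reference_mass: float) -> float:
    """Convert a relative tolerance in parts-per-million to Da at a mass."""
    return ppm * 1e-6 * reference_mass


@dataclass(frozen=True)
class Subunit:
    name: str
    mass: float
    max_copies: int

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ParameterError(f"subunit {self.name!r}: mass must be > 0")
        if int(self.max_copies) != self.max_copies or self.max_copies < 1:
            raise ParameterError(
                f"subunit {self.name!r}: max_copies must be a positive integer"
            )


@dataclass(frozen=True)
class SubunitTable:
    """Known subunits: unique names, positive average masses, copy bounds."""

    entries: tuple[Subunit, ...]

    def __post_init__(self) -> None:
        entries = tuple(
            e if isinstance(e, Subunit) else Subunit(*e) for e in self.entries
        )
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ParameterError(f"subunit names must be unique, got {names}")
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_mapping(cls, d: Mapping[str, tuple[float, int]]) -> "SubunitTable":
        """Build from ``{name: (mass, max_copies)}``."""
        return cls(tuple(Subunit(n, m, c) for n, (m, c) in d.items()))


@dataclass(frozen=True)
class StoichiometrySolution:
    """One matching copy-number vector.

    ``deviation`` is signed: total_mass - target, in Da.
    """

    counts: Mapping[str, int]
    total_mass: float
    deviation: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))


def enumerate_stoichiometries(
    subunits: SubunitTable, target: float, tolerance: float
) -> list[StoichiometrySolution]:
    """All bounded copy-number vectors with total mass within tolerance of target.

    At least one copy overall is required (the empty complex is not a
    solution).  Results are sorted by absolute deviation ascending, ties
    broken lexicographically on the count vector in table order.  Pruning is
    an optimization only: the returned set equals full enumeration.
    """
    if not len(subunits):
        raise ParameterError("subunit table is empty")
    if not target > 0:
        raise ParameterError(f"target mass must be > 0, got {target}")
    if tolerance < 0:
        raise ParameterError(f"tolerance must be >= 0, got {tolerance}")

    space = 1
    for e in subunits.entries:
        space *= e.max_copies + 1
        if space > MAX_SEARCH_NODES:
            raise ComplexityError(
                f"search space exceeds {MAX_SEARCH_NODES:.0e} nodes; "
                "tighten per-subunit max_copies"
            )

    entries = subunits.entries
    n = len(entries)
    hi = target + tolerance
    lo = target - tolerance
    # max mass still addable from subunit i onward — for lower-bound pruning
    tail_max = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        tail_max[i] = tail_max[i + 1] + entries[i].mass * entries[i].max_copies

    out: list[StoichiometrySolution] = []
    counts = [0] * n

    def recurse(i: int, partial: float) -> None:
        if partial > hi:  # cannot decrease: prune
            return
        if partial + tail_max[i] < lo:  # cannot reach target: prune
            return
        if i == n:
            if lo <= partial <= hi and any(counts):
                out.append(
                    StoichiometrySolution(
                        counts={e.name: c for e, c in zip(entries, counts)},
                        total_mass=partial,
                        deviation=partial - target,
                    )
                )
            return
        m = entries[i].mass
        for c in range(entries[i].max_copies + 1):
            s = partial + c * m
            if s > hi:
                break
            counts[i] = c
            recurse(i + 1, s)
        counts[i] = 0

    recurse(0, 0.0)
    order = [e.name for e in entries]
    out.sort(key=lambda sol: (abs(sol.deviation),
                              tuple(sol.counts[name] for name in order)))
    return out


def score_series_against_subunits(
    series: ChargeSeries, subunits: SubunitTable, tolerance: float
) -> list[StoichiometrySolution]:
    """Match an assigned series' mass against the subunit table.

    The effective tolerance is ``max(tolerance, 3 * series.uncertainty)``
    so a poorly determined mass is not matched more tightly than its own
    standard deviation supports.
    """
    eff = max(float(tolerance), 3.0 * series.uncertainty)
    return enumerate_stoichiometries(subunits, target=series.mass, tolerance=eff)
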