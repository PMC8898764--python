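"""Heisenberg double-exchange (HDE) spin ladder of a mixed-valent dimer.

A d5-d6 pair such as [Fe2Q2]+ carries local spins (s_a, s_b) = (5/2, 2)
coupled by Heisenberg exchange J (-2J S1.S2 convention, J < 0
antiferromagnetic).  Resonance delocalization of the itinerant electron
(double exchange, B) splits every total-spin level S into a symmetric and an
antisymmetric branch:

    E_pm(S) = -J S(S+1) +/- B (S + 1/2)

For J < 0 the ground spin steps from 1/2 up to s_a + s_b as |B/J| grows,
with crossings at |B/J| = 2(S+1); intermediate ground spins 3/2, 5/2, 7/2
occupy 3 <= |B/J| <= 9 for the default pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LocalSpinPair",
    "ExchangeSystem",
    "SpinLevel",
    "SpinLadder",
    "hde_energies",
    "ground_spin",
    "crossing_ratios",
    "phase_diagram",
]


def _is_half_integer(x: float) -> bool:
    return abs(2 * x - round(2 * x)) < 1e-12


@dataclass(frozen=True)
class LocalSpinPair:
    """Local spin quantum numbers of the two metal sites.

    Defaults to the high-spin ferric/ferrous pair (5/2, 2).
    """

    s_a: float = 2.5
    s_b: float = 2.0

    def __post_init__(self) -> None:
        for name in ("s_a", "s_b"):
            v = getattr(self, name)
            if v < 0 or not _is_half_integer(v):
                raise ValueError(
                    f"{name}={v!r}: local spins must be non-negative integers "
                    "or half-integers"
                )

    @property
    def allowed_spins(self) -> np.ndarray:
        """Total spins |s_a - s_b| ... s_a + s_b in unit steps."""
        lo, hi = abs(self.s_a - self.s_b), self.s_a + self.s_b
        n = int(round(hi - lo)) + 1
        return lo + np.arange(n, dtype=float)


@dataclass(frozen=True)
class ExchangeSystem:
    """HDE Hamiltonian parameters: Heisenberg J and double exchange B (cm^-1).

    B enters the spectrum only through |B|; a signed B is absolute-valued
    with a warning.  J < 0 is antiferromagnetic.
    """

    spins: LocalSpinPair = field(default_factory=LocalSpinPair)
    J: float = -1.0
    B: float = 0.0

    def __post_init__(self) -> None:
        if self.B < 0:
            warnings.warn(
                "double-exchange B is a magnitude; taking |B|", stacklevel=3
            )
            object.__setattr__(self, "B", abs(self.B))

    @property
    def ratio(self) -> float:
        """|B/J|; infinity when J = 0 and B > 0, 0 when both vanish."""
        if self.J == 0:
            return np.inf if self.B > 0 else 0.0
        return abs(self.B / self.J)


@dataclass(frozen=True)
class SpinLevel:
    S: float
    branch: str  # '+' or '-'
    energy: float  # cm^-1

    @property
    def degeneracy(self) -> int:
        return int(round(2 * self.S + 1))


@dataclass(frozen=True)
class SpinLadder:
    """All (S, branch) levels of an ExchangeSystem, sorted by energy."""

    system: ExchangeSystem
    levels: tuple[SpinLevel, ...]

    @property
    def n_states(self) -> int:
        return sum(lv.degeneracy for lv in self.levels)

    def energies(self) -> np.ndarray:
        return np.array([lv.energy for lv in self.levels])

    def ground_level(self, atol: float = 1e-9) -> tuple[SpinLevel, bool]:
        """Minimum-energy level and a degeneracy flag.

        Ties (within ``atol``) are broken toward the lower total spin, then
        the '-' branch; the flag reports whether a distinct-S level is
        degenerate with the winner.
        """
        ordered = sorted(
            self.levels, key=lambda lv: (lv.energy, lv.S, lv.branch != "-")
        )
        g = ordered[0]
        degenerate = any(
            abs(lv.energy - g.energy) <= atol and lv.S != g.S
            for lv in ordered[1:]
        )
        return g, degenerate


def hde_energies(system: ExchangeSystem) -> SpinLadder:
    """Construct the HDE ladder E_pm(S) = -J S(S+1) +/- B(S+1/2)."""
    levels = []
    for S in system.spins.allowed_spins:
        e0 = -system.J * S * (S + 1.0)
        split = system.B * (S + 0.5)
        levels.append(SpinLevel(S, "-", e0 - split))
        levels.append(SpinLevel(S, "+", e0 + split))
    levels.sort(key=lambda lv: (lv.energy, lv.S, lv.branch != "-"))
    return SpinLadder(system, tuple(levels))


def ground_spin(system: ExchangeSystem) -> float:
    """Total spin S of the minimum-energy level (lower-S tie-break)."""
    g, _ = hde_energies(system).ground_level()
    return g.S


def crossing_ratios(spins: LocalSpinPair | None = None) -> list[float]:
    """|B/J| values at which the J < 0 ground spin steps from S to S+1.

    Adjacent '-'-branch levels cross where |J| 2(S+1) = B, i.e. at
    |B/J| = 2(S+1); for (5/2, 2) this gives {3, 5, 7, 9}.  Empty when only
    one total spin is allowed.
    """
    spins = spins or LocalSpinPair()
    allowed = spins.allowed_spins
    return [2.0 * (S + 1.0) for S in allowed[:-1]]


def phase_diagram(
    spins: LocalSpinPair | None = None,
    ratios: Sequence[float] | np.ndarray = (),
    j_sign: int = -1,
) -> dict[float, float]:
    """Ground spin versus |B/J| for fixed sign of J.

    For J > 0 the ferromagnetic maximum spin wins at every ratio; for J < 0
    the mapping is a non-decreasing step function with steps at 2(S+1).
    """
    spins = spins or LocalSpinPair()
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios < 0):
        raise ValueError("|B/J| ratios must be non-negative")
    if j_sign not in (-1, 1):
        raise ValueError("j_sign must be +1 or -1")
    J = float(j_sign)
    return {
        float(r): ground_spin(ExchangeSystem(spins, J=J, B=r))
        for r in ratios
    }
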