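"""Zero-field splitting, effective g values, nutation and doublet populations.

The spin Hamiltonian of an isolated S manifold in a field B (tesla) is

    H = D [Sz^2 - S(S+1)/3] + E (Sx^2 - Sy^2) + mu_B sum_k g_k B_k S_k

with axial D and rhombic E = (E/D) D in cm^-1, rhombicity E/D in the
canonical range [0, 1/3].  Half-integer S yields Kramers doublets at zero
field; an isolated doublet behaves as a fictitious S' = 1/2 with effective
g' values given, in the large-|D| first-order Zeeman limit, by the splitting
of the doublet under an infinitesimal field along each principal axis.

For S = 3/2 the two zero-field doublets sit at -/+ sqrt(D^2 + 3E^2); in the
axial limit (E/D = 0, D > 0) the lower Ms = +/-1/2 doublet shows the
textbook (2g, 2g, g) pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import G_E, HBAR_SI, KB_CM, MUB_CM_PER_T, MUB_SI

__all__ = [
    "ZFSSystem",
    "EffectiveG",
    "NutationSpec",
    "spin_matrices",
    "zfs_hamiltonian",
    "zero_field_doublets",
    "doublet_effective_g",
    "rhombogram",
    "nutation_frequency",
    "nutation_ratio",
    "doublet_population",
]

_AXES = ("x", "y", "z")


def spin_matrices(S: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Sx, Sy, Sz) in the |S, m> basis, m = S ... -S (complex arrays)."""
    dim = int(round(2 * S + 1))
    if abs((dim - 1) / 2 - S) > 1e-12 or S < 0:
        raise ValueError(f"S={S!r} is not a valid spin quantum number")
    m = S - np.arange(dim)
    sz = np.diag(m).astype(complex)
    sp = np.zeros((dim, dim), dtype=complex)
    for i in range(1, dim):
        sp[i - 1, i] = np.sqrt(S * (S + 1) - m[i] * (m[i] + 1))
    sx = (sp + sp.conj().T) / 2.0
    sy = (sp - sp.conj().T) / 2.0j
    return sx, sy, sz


@dataclass(frozen=True)
class ZFSSystem:
    """Spin S with axial ZFS D (cm^-1, signed), rhombicity E/D, intrinsic g.

    ``g`` may be a scalar (isotropic) or three principal values (gx, gy, gz)
    in the ZFS frame.  E/D outside [0, 1/3] is rejected: rotate the tensor
    into the canonical convention first.
    """

    S: float = 1.5
    D: float = 0.0
    E_over_D: float = 0.0
    g: float | Sequence[float] = G_E

    def __post_init__(self) -> None:
        spin_matrices(self.S)  # validates S
        if not 0.0 <= self.E_over_D <= 1.0 / 3.0 + 1e-12:
            raise ValueError(
                f"E_over_D={self.E_over_D!r} outside the canonical range "
                "[0, 1/3]"
            )
        gv = np.atleast_1d(np.asarray(self.g, dtype=float))
        if gv.size == 1:
            gv = np.repeat(gv, 3)
        if gv.shape != (3,) or np.any(gv < 0):
            raise ValueError("g must be a non-negative scalar or 3 principal values")
        object.__setattr__(self, "g", tuple(gv))

    @property
    def E(self) -> float:
        return self.E_over_D * self.D

    @property
    def is_kramers(self) -> bool:
        return int(round(2 * self.S)) % 2 == 1

    @property
    def n_doublets(self) -> int:
        return int(round(2 * self.S + 1)) // 2


def zfs_hamiltonian(
    zfs: ZFSSystem, field: Sequence[float] | np.ndarray = (0.0, 0.0, 0.0)
) -> np.ndarray:
    """Hermitian (2S+1)-dimensional H(B) in cm^-1, field in tesla."""
    sx, sy, sz = spin_matrices(zfs.S)
    eye = np.eye(sx.shape[0])
    h = zfs.D * (sz @ sz - zfs.S * (zfs.S + 1) / 3.0 * eye)
    h = h + zfs.E * (sx @ sx - sy @ sy)
    b = np.asarray(field, dtype=float)
    for gk, bk, sk in zip(zfs.g, b, (sx, sy, sz)):
        if bk != 0.0:
            h = h + MUB_CM_PER_T * gk * bk * sk
    return h


def zero_field_doublets(zfs: ZFSSystem) -> tuple[np.ndarray, np.ndarray]:
    """Zero-field doublet energies (ascending) and eigenvector columns.

    Requires half-integer S (Kramers theorem guarantees exact two-fold
    degeneracy); eigenvectors are returned grouped in energy order.
    """
    if not zfs.is_kramers:
        raise ValueError(
            f"S={zfs.S} is an integer spin: zero-field levels are not "
            "Kramers doublets; effective-g analysis applies to half-integer S"
        )
    w, v = np.linalg.eigh(zfs_hamiltonian(zfs))
    energies = w.reshape(-1, 2).mean(axis=1)
    return energies, v


@dataclass(frozen=True)
class EffectiveG:
    doublet: int  # 0 = lowest zero-field doublet
    energy: float  # zero-field energy, cm^-1
    g_axes: tuple[float, float, float]  # (g'_x, g'_y, g'_z)

    @property
    def g_sorted(self) -> tuple[float, float, float]:
        """Effective g values sorted descending."""
        return tuple(sorted(self.g_axes, reverse=True))

    @property
    def labeled(self) -> list[tuple[float, str]]:
        """(g', axis) pairs sorted descending."""
        return sorted(zip(self.g_axes, _AXES), reverse=True)


def doublet_effective_g(
    zfs: ZFSSystem, doublet: int = 0, method: str = "first_order", b_probe: float = 0.01
) -> EffectiveG:
    """Effective g' of one Kramers doublet.

    ``method="first_order"`` (default) projects the Zeeman operator onto the
    zero-field doublet subspace — the exact B -> 0 slope, valid when
    |D| >> mu_B B.  ``method="finite"`` diagonalizes the full matrix at the
    probe field ``b_probe`` (tesla) and divides the level splitting by
    mu_B B, for finite-D comparison.
    """
    energies, v = zero_field_doublets(zfs)
    if not 0 <= doublet < zfs.n_doublets:
        raise ValueError(f"doublet index {doublet} out of range")
    sx, sy, sz = spin_matrices(zfs.S)
    gvals = []
    if method == "first_order":
        p = v[:, 2 * doublet : 2 * doublet + 2]
        for gk, sk in zip(zfs.g, (sx, sy, sz)):
            w = np.linalg.eigvalsh(p.conj().T @ (gk * sk) @ p)
            gvals.append(float(w[-1] - w[0]))
    elif method == "finite":
        for k in range(3):
            b = np.zeros(3)
            b[k] = b_probe
            w = np.linalg.eigvalsh(zfs_hamiltonian(zfs, b))
            lo, hi = w[2 * doublet], w[2 * doublet + 1]
            gvals.append(float((hi - lo) / (MUB_CM_PER_T * b_probe)))
    else:
        raise ValueError("method must be 'first_order' or 'finite'")
    return EffectiveG(doublet, float(energies[doublet]), tuple(gvals))


def rhombogram(
    S: float = 1.5,
    g: float | Sequence[float] = G_E,
    eta_grid: Sequence[float] | np.ndarray | None = None,
    D: float = 1.0,
):
    """Effective g' versus rhombicity eta = E/D for every doublet.

    Returns a pandas DataFrame with columns (eta, doublet, gx, gy, gz);
    the sign of D fixes the doublet energy order.
    """
    import pandas as pd

    if eta_grid is None:
        eta_grid = np.linspace(0.0, 1.0 / 3.0, 101)
    eta_grid = np.asarray(eta_grid, dtype=float)
    if np.any(eta_grid < 0) or np.any(eta_grid > 1.0 / 3.0 + 1e-12):
        raise ValueError("eta grid must lie within [0, 1/3]")
    rows = []
    for eta in eta_grid:
        zfs = ZFSSystem(S=S, D=D, E_over_D=float(eta), g=g)
        for d in range(zfs.n_doublets):
            eff = doublet_effective_g(zfs, d)
            rows.append((float(eta), d, *eff.g_axes))
    return pd.DataFrame(rows, columns=["eta", "doublet", "gx", "gy", "gz"])


@dataclass(frozen=True)
class NutationSpec:
    """Driven-spin (Rabi) nutation: Omega = g1 mu_B B1 / hbar * sqrt(S(S+1))."""

    S: float
    g1: float = G_E
    B1: float = 1.0e-4  # microwave field amplitude, tesla

    def __post_init__(self) -> None:
        if self.B1 < 0:
            raise ValueError("B1 must be >= 0")


def nutation_frequency(spec: NutationSpec) -> float:
    """Nutation angular frequency Omega_nut in rad s^-1."""
    return (
        spec.g1 * MUB_SI * spec.B1 / HBAR_SI * np.sqrt(spec.S * (spec.S + 1.0))
    )


def nutation_ratio(S_a: float, S_b: float) -> float:
    """Omega(S_a)/Omega(S_b) at equal g1 B1 — the spin-assignment ratio."""
    return float(np.sqrt(S_a * (S_a + 1.0) / (S_b * (S_b + 1.0))))


def doublet_population(zfs: ZFSSystem, T: float) -> np.ndarray:
    """Boltzmann fractions of the zero-field Kramers doublets at T (kelvin).

    Each doublet carries degeneracy 2; fractions are ordered by energy and
    sum to 1.
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    energies, _ = zero_field_doublets(zfs)
    w = 2.0 * np.exp(-(energies - energies.min()) / (KB_CM * T))
    return w / w.sum()
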