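"""Simulation and fitting of SQUID magnetometry observables.

chi_M T of the double-exchange ladder (the Bleaney-Bowers construction for a
d5-d6 mixed-valent centre extended with double exchange) is the van Vleck /
Boltzmann average over all (S, +/-) levels,

    chi_M T = C g^2 * sum (2S+1) S(S+1) exp(-E/kT) / sum (2S+1) exp(-E/kT),

with C = N_A mu_B^2 / (3 k_B) = 0.125049 cm^3 K mol^-1.  The shape of
chi_M T over a finite temperature window constrains the ratio r = |B/J| far
more robustly than J and B separately, so the fitter parameterizes (J, r)
and profiles the residual over r.

Magnetization of a zero-field-split manifold is computed by full
diagonalization of H(B) and the thermal expectation of the moment operator
-dH/dB (no finite differences); powder curves average over a Fibonacci
orientation grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import CURIE_C, KB_CM, MUB_CM_PER_T, NA_MUB_EMU_PER_T
from .ladder import ExchangeSystem, hde_energies
from .zfs import ZFSSystem, spin_matrices, zfs_hamiltonian

__all__ = [
    "MagnetometryCurve",
    "ChiTFitConfig",
    "ChiTFitResult",
    "chi_t",
    "fit_chi_t",
    "zeeman_magnetization",
    "powder_moment",
    "powder_magnetization_curve",
    "chi_t_zfs",
    "mixture_response",
    "fibonacci_sphere",
]


@dataclass
class MagnetometryCurve:
    """Two-column magnetometry series with units.

    kind 'susceptibility': abscissa T (K), ordinate chi_M T (cm^3 K mol^-1).
    kind 'magnetization': abscissa H (T), ordinate M (mu_B per molecule),
    recorded at ``temperature`` kelvin.
    """

    kind: str
    abscissa: np.ndarray
    ordinate: np.ndarray
    temperature: float | None = None
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("susceptibility", "magnetization"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.ordinate = np.asarray(self.ordinate, dtype=float)
        if self.abscissa.shape != self.ordinate.shape or self.abscissa.ndim != 1:
            raise ValueError("abscissa and ordinate must be equal-length 1-d")
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if self.kind == "susceptibility":
            if np.any(self.abscissa <= 0):
                raise ValueError("temperatures must be > 0")
            if np.any(self.ordinate < 0):
                raise ValueError("chi_M T must be >= 0")
        if self.kind == "magnetization":
            if self.temperature is None or self.temperature <= 0:
                raise ValueError("magnetization curves need a temperature > 0")
            if np.any(self.abscissa < 0):
                raise ValueError("fields must be >= 0")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.abscissa.shape:
                raise ValueError("sigma must match the data length")


def chi_t(
    system: ExchangeSystem, g: float, T: Sequence[float] | np.ndarray
) -> np.ndarray:
    """chi_M T (cm^3 K mol^-1) of the HDE ladder on a temperature grid (K)."""
    T = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(T <= 0):
        raise ValueError("temperatures must be > 0")
    ladder = hde_energies(system)
    E = ladder.energies()
    S = np.array([lv.S for lv in ladder.levels])
    deg = 2.0 * S + 1.0
    # shift-invariant, overflow-safe Boltzmann weights
    w = deg[None, :] * np.exp(-(E - E.min())[None, :] / (KB_CM * T[:, None]))
    return CURIE_C * g * g * (w * (S * (S + 1.0))[None, :]).sum(1) / w.sum(1)


@dataclass
class ChiTFitConfig:
    """Settings for fitting chi_M T data with the double-exchange model."""

    t_min: float = 50.0  # fit only T > t_min (K)
    g: float = 2.0
    vary_g: bool = False
    j0: float = -40.0  # starting Heisenberg exchange, cm^-1
    r_starts: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0)
    r_profile: tuple[float, float, float] = (0.2, 10.0, 0.1)  # lo, hi, step
    compute_profile: bool = True  # skip for bulk replicate studies
    allow_low_t: bool = False  # override the T > t_min restriction
    min_points: int = 10


@dataclass
class ChiTFitResult:
    r: float
    r_stderr: float | None
    J: float
    J_stderr: float | None
    g: float
    g_stderr: float | None
    success: bool
    residual_norm: float
    n_points: int
    message: str
    profile_r: np.ndarray
    profile_cost: np.ndarray


def _fit_once(T, y, w, g, vary_g, j0, r0):
    import lmfit

    params = lmfit.Parameters()
    params.add("J", value=j0, max=-1e-3)
    params.add("r", value=r0, min=0.0, max=30.0)
    params.add("g", value=g, min=0.5, max=4.0, vary=vary_g)

    def resid(p):
        sys_ = ExchangeSystem(J=p["J"].value, B=p["r"].value * abs(p["J"].value))
        return (chi_t(sys_, p["g"].value, T) - y) * w

    return lmfit.minimize(resid, params, method="leastsq")


def fit_chi_t(curve: MagnetometryCurve, config: ChiTFitConfig | None = None) -> ChiTFitResult:
    """Weighted least-squares fit of chi_M T against the HDE van Vleck model.

    Restricts to T > t_min (the model ignores vibronic trapping, which
    distorts the low-temperature response), multi-starts over a grid of
    r = |B/J| values, and profiles the residual norm over r with J (and g,
    if free) re-optimized at each fixed r.
    """
    config = config or ChiTFitConfig()
    if curve.kind != "susceptibility":
        raise ValueError("fit_chi_t needs a susceptibility curve")
    mask = (
        np.ones_like(curve.abscissa, dtype=bool)
        if config.allow_low_t
        else curve.abscissa > config.t_min
    )
    T, y = curve.abscissa[mask], curve.ordinate[mask]
    if T.size < config.min_points:
        raise ValueError(
            f"only {T.size} points above t_min={config.t_min} K "
            f"(need >= {config.min_points})"
        )
    if np.ptp(y) < 1e-12:
        raise ValueError("degenerate data: chi_M T is constant over the window")
    w = 1.0 / curve.sigma[mask] if curve.sigma is not None else np.ones_like(y)

    best = None
    for r0 in config.r_starts:
        out = _fit_once(T, y, w, config.g, config.vary_g, config.j0, r0)
        if best is None or out.chisqr < best.chisqr:
            best = out

    if config.compute_profile:
        lo, hi, step = config.r_profile
        prof_r = np.arange(lo, hi + step / 2, step)
    else:
        prof_r = np.array([])
    prof_cost = np.empty_like(prof_r)
    import lmfit

    for i, r in enumerate(prof_r):
        params = lmfit.Parameters()
        params.add("J", value=best.params["J"].value, max=-1e-3)
        params.add("r", value=float(r), vary=False)
        params.add(
            "g", value=best.params["g"].value, min=0.5, max=4.0, vary=config.vary_g
        )

        def resid(p):
            sys_ = ExchangeSystem(J=p["J"].value, B=p["r"].value * abs(p["J"].value))
            return (chi_t(sys_, p["g"].value, T) - y) * w

        prof_cost[i] = lmfit.minimize(resid, params, method="leastsq").chisqr

    pj, pr, pg = best.params["J"], best.params["r"], best.params["g"]
    if abs(pj.value) < 0.05 or (pj.stderr is not None and pj.stderr > abs(pj.value)):
        warnings.warn(
            "Heisenberg J is weakly constrained by this temperature window; "
            "trust the |B/J| ratio, not (J, B) separately",
            stacklevel=2,
        )
    if not best.success:
        warnings.warn(f"chi_M T fit did not converge: {best.message}", stacklevel=2)
    return ChiTFitResult(
        r=float(pr.value),
        r_stderr=pr.stderr,
        J=float(pj.value),
        J_stderr=pj.stderr,
        g=float(pg.value),
        g_stderr=pg.stderr,
        success=bool(best.success),
        residual_norm=float(np.sqrt(best.chisqr)),
        n_points=int(T.size),
        message=str(best.message),
        profile_r=prof_r,
        profile_cost=prof_cost,
    )


def _moment_operator(zfs: ZFSSystem, direction: np.ndarray) -> np.ndarray:
    """-dH/dB along ``direction`` in units of mu_B (dimensionless matrix)."""
    sx, sy, sz = spin_matrices(zfs.S)
    return -sum(
        gk * nk * sk for gk, nk, sk in zip(zfs.g, direction, (sx, sy, sz))
    )


def zeeman_magnetization(
    zfs: ZFSSystem,
    field: float,
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    T: float = 2.0,
) -> float:
    """Thermal moment projection on the field direction, in mu_B.

    Full diagonalization of H = H_ZFS + Zeeman; M is the Boltzmann average
    of the expectation of the moment operator -dH/dB (Hellmann-Feynman),
    not a finite difference.
    """
    if field < 0:
        raise ValueError("field must be >= 0")
    if T <= 0:
        raise ValueError("temperature must be > 0")
    n = np.asarray(direction, dtype=float)
    n = n / np.linalg.norm(n)
    h = zfs_hamiltonian(zfs, field * n)
    w, v = np.linalg.eigh(h)
    m_op = _moment_operator(zfs, n)
    m_diag = np.real(np.einsum("ij,jk,ki->i", v.conj().T, m_op, v))
    p = np.exp(-(w - w.min()) / (KB_CM * T))
    p /= p.sum()
    return float(p @ m_diag)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def powder_moment(
    zfs: ZFSSystem, field: float, T: float = 2.0, n_orient: int = 500
) -> tuple[float, float]:
    """(powder-average M, maximum single-orientation M) in mu_B.

    Averages zeeman_magnetization over a Fibonacci orientation grid; the
    maximum over orientations is the moment along the main magnetization
    axis.  Grids below 50 points are warned against.
    """
    if n_orient < 50:
        warnings.warn(
            f"orientation grid of {n_orient} points is too coarse for a "
            "reliable powder average",
            stacklevel=2,
        )
    dirs = fibonacci_sphere(n_orient)
    m = np.array([zeeman_magnetization(zfs, field, d, T) for d in dirs])
    return float(m.mean()), float(m.max())


def powder_magnetization_curve(
    zfs: ZFSSystem,
    fields: Sequence[float] | np.ndarray,
    T: float = 2.0,
    n_orient: int = 500,
) -> MagnetometryCurve:
    """Powder-average M(H) curve at temperature T."""
    fields = np.asarray(fields, dtype=float)
    m = np.array([powder_moment(zfs, b, T, n_orient)[0] for b in fields])
    return MagnetometryCurve("magnetization", fields, m, temperature=T)


def chi_t_zfs(
    zfs: ZFSSystem,
    T: Sequence[float] | np.ndarray,
    probe_field: float = 0.01,
    n_orient: int = 200,
) -> np.ndarray:
    """chi_M T (cm^3 K mol^-1) of an isolated ZFS manifold, powder-averaged.

    Linear-response estimate from the powder moment at a small probe field:
    chi_M = N_A mu_B M / B.  Reduces to the Curie constant C g^2 S(S+1)
    when D = 0 or k_B T >> |D|.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    out = np.empty_like(T)
    for i, t in enumerate(T):
        m_avg, _ = powder_moment(zfs, probe_field, float(t), n_orient)
        out[i] = NA_MUB_EMU_PER_T * m_avg / probe_field * t
    return out


def mixture_response(
    curves: Sequence[MagnetometryCurve], weights: Sequence[float]
) -> MagnetometryCurve:
    """Convex combination of curves — e.g. a 50:50 frozen-solution mixture
    of S = 1/2 and S = 3/2 spin isomers, per-molecule molar bookkeeping."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be >= 0 and sum to 1")
    if len(curves) != weights.size or not curves:
        raise ValueError("need one weight per curve")
    ref = curves[0]
    for c in curves[1:]:
        if (
            c.kind != ref.kind
            or c.abscissa.shape != ref.abscissa.shape
            or not np.allclose(c.abscissa, ref.abscissa)
        ):
            raise ValueError("curves must share kind and abscissa")
    ord_ = sum(w * c.ordinate for w, c in zip(weights, curves))
    return MagnetometryCurve(
        ref.kind, ref.abscissa.copy(), ord_, temperature=ref.temperature
    )
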