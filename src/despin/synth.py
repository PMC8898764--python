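"""Seed-controlled synthetic magnetometry data for the [Fe2Q2]+ series.

Emulates the SQUID observables the analysis consumes: chi_M T(T) over
2-290 K generated from the double-exchange ladder at the fitted |B/J|
ratios (2.0, 2.9, 3.7 for the S, Se, Te complexes), and powder M(H) at 2 K
over 0.1-7 T for an S = 1/2 centre, a zero-field-split S = 3/2 centre, and
a 50:50 mixture of the two "spin isomers" (the Se complex in frozen
solution).  Noise is multiplicative Gaussian at a relative sigma of 1% by
default, the SQUID relative-error regime.

The published fits constrain only r = |B/J|; fixtures adopt J = -40 cm^-1,
a magnitude typical of [Fe2S2]+ chromophores and consistent with the
weakening antiferromagnetic coupling across the series, with B = r |J|.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .ladder import ExchangeSystem, LocalSpinPair
from .magnetometry import (
    MagnetometryCurve,
    chi_t,
    mixture_response,
    powder_magnetization_curve,
)
from .zfs import ZFSSystem

__all__ = ["MixtureComponent", "GeneratorConfig", "FIXTURES", "fixture_config",
           "generate_chit", "generate_magnetization"]


@dataclass(frozen=True)
class MixtureComponent:
    """One spin isomer of a frozen-solution mixture."""

    zfs: ZFSSystem
    weight: float


def _default_temperatures() -> np.ndarray:
    return np.arange(2.0, 291.0, 2.0)


def _default_fields() -> np.ndarray:
    return np.arange(0.1, 7.0 + 1e-9, 0.1)


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and sampling plan for one synthetic dataset."""

    name: str = "custom"
    J: float = -40.0  # cm^-1
    r: float = 3.7  # |B/J|
    g: float = 2.0
    sigma: float = 0.01  # relative Gaussian noise
    temperatures: np.ndarray = field(default_factory=_default_temperatures)
    fields: np.ndarray = field(default_factory=_default_fields)
    mag_temperature: float = 2.0  # K
    mixture: tuple[MixtureComponent, ...] | None = None
    zfs: ZFSSystem | None = None  # single-component magnetization source
    seed: int = 0
    n_orient: int = 200

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.mixture is not None:
            w = sum(c.weight for c in self.mixture)
            if not np.isclose(w, 1.0):
                raise ValueError("mixture weights must sum to 1")

    @property
    def system(self) -> ExchangeSystem:
        return ExchangeSystem(LocalSpinPair(), J=self.J, B=self.r * abs(self.J))


#: The three [Fe2Q2]+ fixtures: fitted |B/J| and EPR-derived g_iso per
#: complex; the Se complex additionally carries the 50:50 S = 1/2 + S = 3/2
#: spin-isomer mixture (D = +11 cm^-1, E/D = 0.12) seen in frozen solution,
#: and the Te complex the fully rhombic S = 3/2 centre.
FIXTURES: dict[str, dict[str, Any]] = {
    "complex1": dict(
        r=2.0, g=1.90, zfs=ZFSSystem(S=0.5, g=1.90), mixture=None
    ),
    "complex2": dict(
        r=2.9,
        g=1.92,
        zfs=None,
        mixture=(
            MixtureComponent(ZFSSystem(S=0.5, g=1.92), 0.5),
            MixtureComponent(
                ZFSSystem(S=1.5, D=11.0, E_over_D=0.12, g=1.925), 0.5
            ),
        ),
    ),
    "complex3": dict(
        r=3.7,
        g=2.00,
        zfs=ZFSSystem(S=1.5, D=11.0, E_over_D=1.0 / 3.0),
        mixture=None,
    ),
}


def fixture_config(name: str, seed: int = 0, **overrides: Any) -> GeneratorConfig:
    """GeneratorConfig for one of the named fixtures."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    cfg = GeneratorConfig(name=name, seed=seed, **FIXTURES[name])
    return replace(cfg, **overrides) if overrides else cfg


def _add_noise(y: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0.0:
        return y.copy()
    return y * (1.0 + sigma * rng.standard_normal(y.shape))


def generate_chit(config: GeneratorConfig) -> tuple[MagnetometryCurve, dict]:
    """Synthetic chi_M T(T) curve from the HDE ladder, plus ground truth."""
    rng = np.random.default_rng(config.seed)
    clean = chi_t(config.system, config.g, config.temperatures)
    noisy = _add_noise(clean, config.sigma, rng)
    curve = MagnetometryCurve(
        "susceptibility",
        config.temperatures.copy(),
        noisy,
        sigma=config.sigma * clean if config.sigma > 0 else None,
    )
    truth = dict(
        name=config.name, J=config.J, r=config.r, g=config.g,
        sigma=config.sigma, seed=config.seed, model="hde_van_vleck",
    )
    return curve, truth


def generate_magnetization(config: GeneratorConfig) -> tuple[MagnetometryCurve, dict]:
    """Synthetic powder M(H) at 2 K, single centre or spin-isomer mixture."""
    rng = np.random.default_rng(config.seed)
    if config.mixture is not None:
        comps = [
            powder_magnetization_curve(
                c.zfs, config.fields, config.mag_temperature, config.n_orient
            )
            for c in config.mixture
        ]
        clean_curve = mixture_response(comps, [c.weight for c in config.mixture])
        model = "powder_zfs_mixture"
    else:
        if config.zfs is None:
            raise ValueError("config needs a ZFSSystem or a mixture")
        clean_curve = powder_magnetization_curve(
            config.zfs, config.fields, config.mag_temperature, config.n_orient
        )
        model = "powder_zfs"
    noisy = _add_noise(clean_curve.ordinate, config.sigma, rng)
    curve = MagnetometryCurve(
        "magnetization",
        clean_curve.abscissa,
        noisy,
        temperature=config.mag_temperature,
        sigma=config.sigma * clean_curve.ordinate if config.sigma > 0 else None,
    )
    truth = dict(
        name=config.name, sigma=config.sigma, seed=config.seed, model=model,
        temperature=config.mag_temperature,
    )
    return curve, truth
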