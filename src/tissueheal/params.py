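"""Material, biological and simulation parameters with SI units.

All energies are per unit mass (J/kg), densities per unit reference volume
(kg/m^3), rates per second. One year is 3.1536e7 s (365 days); table values
quoted per year are converted with this factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

__all__ = [
    "YEAR",
    "DAY",
    "MaterialParams",
    "BioParams",
    "species_study_params",
    "biaxial_params",
    "indentation_params",
    "load_config",
    "dump_config",
]

YEAR = 3.1536e7  # s (365 days)
DAY = 86400.0  # s


@dataclass(frozen=True)
class BioParams:
    """Parameters of the MMP / growth-factor / collagen-turnover ODE system.

    M0, G0   homeostatic MMP and GF concentrations        [kg/m^3]
    m1       MMP production per unit damaged-collagen     [kg/(m^3 s)]
    m2       MMP decay rate toward M0                      [1/s]
    g1       GF production rate from accumulated MMP       [1/s]
    g2       GF decay rate toward G0                       [1/s]
    t_decay  saturation time of the accumulated-MMP signal [s]
    kd1,kd2  degradation law of damaged collagen
    ki1,ki2  deposition law of intact collagen
    """

    M0: float = 5.6e-5
    G0: float = 3.5e-5
    m1: float = 4e-11
    m2: float = 1e-6
    g1: float = 1e-4
    g2: float = 4.63e-5
    t_decay: float = 0.5 * YEAR
    kd1: float = 1e-4
    kd2: float = 10.0
    ki1: float = 1e-4
    ki2: float = 2.0

    def __post_init__(self):
        for k, v in asdict(self).items():
            if not v > 0:
                raise ValueError(f"BioParams.{k} must be positive")


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive, damage, remodeling and growth-penalty parameters.

    mu         matrix (Neo-Hooke) shear stiffness per unit mass  [J/kg]
    k1, k2     collagen exponential law                          [J/kg], [-]
    kappa      growth-constraint penalty stiffness               [J/kg]
    rho0_init  initial total reference density rho_0(0)          [kg/m^3]
    phi_c0     initial collagen mass fraction                    [-]
    lambda_pre collagen deposition pre-stretch                   [-]
    k_rem      remodeling gain                                   [1/s]
    m_p        damage slope                                      [-]
    lambda_bar_p  collagen stretch threshold for damage          [-]
    """

    mu: float = 115.0
    k1: float = 2.0
    k2: float = 3.2
    kappa: float = 1e7
    rho0_init: float = 1050.0
    phi_c0: float = 0.8
    lambda_pre: float = 1.062
    k_rem: float = 0.8 / YEAR
    m_p: float = 2.5
    lambda_bar_p: float = 1.3
    bio: BioParams = field(default_factory=BioParams)

    def __post_init__(self):
        scalars = {k: v for k, v in self.__dict__.items() if k != "bio"}
        for k, v in scalars.items():
            if not v > 0:
                raise ValueError(f"MaterialParams.{k} must be positive")
        if not 0 < self.phi_c0 < 1:
            raise ValueError("phi_c0 must lie in (0, 1)")
        if not self.lambda_pre > 1:
            raise ValueError("lambda_pre must exceed 1")
        if not self.lambda_bar_p > 1:
            raise ValueError("lambda_bar_p must exceed 1")

    @property
    def rho_c0(self) -> float:
        """Initial collagen reference density."""
        return self.phi_c0 * self.rho0_init

    @property
    def rho_m(self) -> float:
        """Matrix reference density (constant in time)."""
        return (1.0 - self.phi_c0) * self.rho0_init


def species_study_params() -> MaterialParams:
    """Parameter set of the single-material-point species study."""
    return MaterialParams(bio=BioParams())


def biaxial_params() -> MaterialParams:
    """Parameter set of the biaxial tension test (note the doubled intact
    collagen deposition rate ki1, deliberately high)."""
    return MaterialParams(bio=BioParams(ki1=2.0e-4))


def indentation_params() -> MaterialParams:
    """Parameter set of the indentation test: stiffer collagen, stiffer
    penalty, lower damage threshold, faster GF dynamics."""
    return MaterialParams(
        k1=10.0,
        kappa=1e8,
        m_p=4.5,
        lambda_bar_p=1.1,
        bio=BioParams(g1=2e-4, g2=6.94e-5),
    )


_BIO_KEYS = set(BioParams.__dataclass_fields__)
_MAT_KEYS = set(MaterialParams.__dataclass_fields__) - {"bio"}


def load_config(path: str | Path) -> MaterialParams:
    """Read a YAML parameter file; keys mirror the dataclass field names.

    A flat mapping is accepted: biological keys are routed to BioParams.
    Unknown keys raise, so incomplete or misspelled tables are caught early.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    bio_kwargs = {k: float(v) for k, v in data.items() if k in _BIO_KEYS}
    mat_kwargs = {k: float(v) for k, v in data.items() if k in _MAT_KEYS}
    unknown = set(data) - _BIO_KEYS - _MAT_KEYS
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    return MaterialParams(bio=BioParams(**bio_kwargs), **mat_kwargs)


def dump_config(params: MaterialParams, path: str | Path) -> None:
    flat = {k: getattr(params, k) for k in _MAT_KEYS}
    flat.update({k: getattr(params.bio, k) for k in _BIO_KEYS})
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))


def with_bio(params: MaterialParams, **kwargs) -> MaterialParams:
    """Copy of ``params`` with selected biological parameters replaced."""
    return replace(params, bio=replace(params.bio, **kwargs))
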