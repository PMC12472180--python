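"""Dissolved greenhouse gases and air-water exchange.

Three computations:

1. **Headspace back-calculation.**  A water sample is partly displaced with
   helium and shaken to equilibrium; the analyte partitions between the
   headspace (ideal gas) and the residual water (Henry's law).  The original
   dissolved concentration follows from mass balance:

       C0 * Vw = x*P * Vh / (R*T)  +  K(T,S) * x*P * Vw

   with x the measured headspace mole fraction, P the equilibration pressure,
   Vh/Vw the headspace/water volumes, and K the solubility
   (mol L^-1 atm^-1).  The inversion is exactly linear in x.

2. **Percent saturation.**  Dissolved concentration relative to the
   air-equilibrium value K(T,S) * x_atm * P_ambient.  At >3800 m altitude the
   ambient pressure (~0.64 atm) matters: equilibrium concentrations are about
   a third lower than at sea level, so the default pressure is configurable
   and deliberately prominent.

3. **Floating-chamber flux.**  OLS slope of chamber mole fraction versus
   time, converted to an areal flux with the ideal-gas molar density:

       flux = slope[ppm/min] * 1e-6 * P/(R*T) * V / A * 60  (µmol m^-2 h^-1)

   positive = emission to the atmosphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError
from .solubility import equilibrium_solubility

__all__ = [
    "GasSample",
    "DissolvedGasResult",
    "ChamberSeries",
    "FluxEstimate",
    "headspace_to_dissolved",
    "partition_to_headspace",
    "saturation_percent",
    "dissolved_gas_result",
    "chamber_flux",
    "R_L_ATM",
    "DEFAULT_ATMOSPHERE_PPM",
    "DEFAULT_PRESSURE_ATM",
]

#: Ideal-gas constant, L atm mol^-1 K^-1.
R_L_ATM = 0.0820573661

#: Modern global-mean dry-air mole fractions (ppm), configurable per run.
DEFAULT_ATMOSPHERE_PPM = {"CO2": 420.0, "CH4": 1.9, "N2O": 0.335}

#: Default ambient pressure (atm) for a >3800 m a.s.l. site.
DEFAULT_PRESSURE_ATM = 0.64

#: Reporting units per gas: micromolar for CO2, nanomolar for CH4/N2O.
_UNIT_FACTOR = {"CO2": 1e6, "CH4": 1e9, "N2O": 1e9}
_UNIT_NAME = {"CO2": "uM", "CH4": "nM", "N2O": "nM"}


@dataclass(frozen=True)
class GasSample:
    """One headspace-equilibrated vial measurement."""

    gas: str
    headspace_ppm: float
    vial_volume_ml: float
    headspace_volume_ml: float
    temp_c: float
    salinity: float
    pressure_atm: float = DEFAULT_PRESSURE_ATM
    timestamp: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.headspace_volume_ml < self.vial_volume_ml):
            raise ValidationError("need 0 < headspace volume < vial volume")
        if self.headspace_ppm < 0:
            raise ValidationError("headspace mole fraction must be non-negative")
        if self.pressure_atm <= 0:
            raise ValidationError("pressure must be positive")

    @property
    def water_volume_ml(self) -> float:
        return self.vial_volume_ml - self.headspace_volume_ml


@dataclass(frozen=True)
class DissolvedGasResult:
    """Dissolved concentration with its air-equilibrium reference.

    ``concentration`` is in the gas's reporting unit (µM for CO2, nM for
    CH4/N2O); ``concentration_mol_l`` is the same number in mol L^-1.
    ``status`` is 'supersaturated', 'equilibrium' or 'subsaturated' by the
    100% threshold.
    """

    gas: str
    concentration: float
    unit: str
    concentration_mol_l: float
    equilibrium_concentration: float | None = None
    saturation_pct: float | None = None
    status: str | None = None
    timestamp: str = ""
    replicate: str = ""


def headspace_to_dissolved(sample: GasSample) -> DissolvedGasResult:
    """Invert the headspace equilibration to the original dissolved concentration."""
    k = equilibrium_solubility(sample.gas, sample.temp_c, sample.salinity)
    t_k = sample.temp_c + 273.15
    vw_l = sample.water_volume_ml / 1000.0
    vh_l = sample.headspace_volume_ml / 1000.0
    p_gas = sample.headspace_ppm * 1e-6 * sample.pressure_atm  # partial pressure, atm
    moles_headspace = p_gas * vh_l / (R_L_ATM * t_k)
    moles_residual = k * p_gas * vw_l
    c0 = (moles_headspace + moles_residual) / vw_l  # mol L^-1
    if c0 < 0:
        raise ValidationError("computed dissolved concentration is negative")
    unit = _UNIT_NAME[sample.gas.upper()]
    return DissolvedGasResult(
        gas=sample.gas.upper(),
        concentration=c0 * _UNIT_FACTOR[sample.gas.upper()],
        unit=unit,
        concentration_mol_l=c0,
        timestamp=sample.timestamp,
        replicate=sample.replicate,
    )


def partition_to_headspace(
    c0_mol_l: float,
    gas: str,
    temp_c: float,
    salinity: float,
    vial_volume_ml: float,
    headspace_volume_ml: float,
    pressure_atm: float = DEFAULT_PRESSURE_ATM,
) -> float:
    """Forward model: headspace mole fraction (ppm) after equilibrating a
    water sample of original dissolved concentration ``c0_mol_l``.

    Exact inverse of `headspace_to_dissolved`; used by the synthetic
    generator and the round-trip tests.
    """
    if c0_mol_l < 0:
        raise DomainError("dissolved concentration must be non-negative")
    if not (0 < headspace_volume_ml < vial_volume_ml):
        raise DomainError("need 0 < headspace volume < vial volume")
    k = equilibrium_solubility(gas, temp_c, salinity)
    t_k = temp_c + 273.15
    vw_l = (vial_volume_ml - headspace_volume_ml) / 1000.0
    vh_l = headspace_volume_ml / 1000.0
    p_gas = c0_mol_l * vw_l / (k * vw_l + vh_l / (R_L_ATM * t_k))
    return p_gas / pressure_atm * 1e6


def saturation_percent(
    concentration_mol_l: float,
    gas: str,
    temp_c: float,
    salinity: float,
    atmospheric_ppm: float | None = None,
    pressure_atm: float = DEFAULT_PRESSURE_ATM,
) -> tuple[float, float, str]:
    """Percent saturation relative to air equilibrium at in-situ T, S, P.

    Returns ``(saturation_pct, equilibrium_mol_l, status)`` where status is
    'supersaturated' (>100%), 'equilibrium' (==100%) or 'subsaturated'.
    """
    gas = gas.upper()
    if atmospheric_ppm is None:
        atmospheric_ppm = DEFAULT_ATMOSPHERE_PPM[gas]
    if atmospheric_ppm <= 0:
        raise DomainError("atmospheric mole fraction must be positive")
    if concentration_mol_l < 0:
        raise DomainError("dissolved concentration must be non-negative")
    k = equilibrium_solubility(gas, temp_c, salinity)
    c_eq = k * atmospheric_ppm * 1e-6 * pressure_atm
    if c_eq <= 0:
        raise DomainError("equilibrium concentration is zero")
    pct = 100.0 * concentration_mol_l / c_eq
    status = (
        "supersaturated" if pct > 100 else "subsaturated" if pct < 100 else "equilibrium"
    )
    return pct, c_eq, status


def dissolved_gas_result(
    sample: GasSample, atmospheric_ppm: float | None = None
) -> DissolvedGasResult:
    """Back-calculate a vial and attach its saturation classification."""
    base = headspace_to_dissolved(sample)
    pct, c_eq, status = saturation_percent(
        base.concentration_mol_l,
        sample.gas,
        sample.temp_c,
        sample.salinity,
        atmospheric_ppm,
        sample.pressure_atm,
    )
    return DissolvedGasResult(
        gas=base.gas,
        concentration=base.concentration,
        unit=base.unit,
        concentration_mol_l=base.concentration_mol_l,
        equilibrium_concentration=c_eq * _UNIT_FACTOR[base.gas],
        saturation_pct=pct,
        status=status,
        timestamp=base.timestamp,
        replicate=base.replicate,
    )


@dataclass(frozen=True)
class ChamberSeries:
    """A floating-chamber accumulation time series for one gas."""

    gas: str
    times_min: np.ndarray
    mole_fraction_ppm: np.ndarray
    chamber_volume_l: float
    chamber_area_m2: float
    temp_c: float
    pressure_atm: float = DEFAULT_PRESSURE_ATM

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_min", np.asarray(self.times_min, dtype=float))
        object.__setattr__(
            self, "mole_fraction_ppm", np.asarray(self.mole_fraction_ppm, dtype=float)
        )
        t = self.times_min
        if t.size < 3:
            raise ValidationError("chamber series needs at least 3 timepoints")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("chamber times must be strictly increasing")
        if t.size != self.mole_fraction_ppm.size:
            raise ValidationError("times and mole fractions must be equal length")
        if self.chamber_volume_l <= 0 or self.chamber_area_m2 <= 0:
            raise ValidationError("chamber geometry must be positive")


Classification = Literal["accumulation", "loss", "no-trend"]


@dataclass(frozen=True)
class FluxEstimate:
    """Areal gas flux from a chamber deployment.

    ``flux`` in µmol m^-2 h^-1, positive = emission; ``classification`` is
    'no-trend' when the slope is indistinguishable from zero at ``alpha``.
    """

    gas: str
    flux: float
    flux_se: float
    slope_ppm_per_min: float
    slope_se: float
    r_squared: float
    p_value: float
    classification: Classification
    n_points: int
    alpha: float


def chamber_flux(series: ChamberSeries, alpha: float = 0.05) -> FluxEstimate:
    """OLS chamber-headspace slope converted to an areal flux.

    The slope t-test against zero drives the classification; an exactly
    constant series (zero residual variance, zero slope) is 'no-trend'.
    """
    t, y = series.times_min, series.mole_fraction_ppm
    res = stats.linregress(t, y)
    slope, se = float(res.slope), float(res.stderr)

    fitted = res.intercept + res.slope * t
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot

    if se == 0.0:
        p = 1.0 if slope == 0.0 else 0.0
    else:
        p = float(res.pvalue)

    t_k = series.temp_c + 273.15
    molar_density = series.pressure_atm / (R_L_ATM * t_k)  # mol L^-1
    conv = 1e-6 * molar_density * series.chamber_volume_l / series.chamber_area_m2
    flux = slope * conv * 60.0 * 1e6  # µmol m^-2 h^-1
    flux_se = se * conv * 60.0 * 1e6

    if p >= alpha or slope == 0.0:
        cls: Classification = "no-trend"
    else:
        cls = "accumulation" if slope > 0 else "loss"

    return FluxEstimate(
        gas=series.gas,
        flux=flux,
        flux_se=flux_se,
        slope_ppm_per_min=slope,
        slope_se=se,
        r_squared=max(min(r2, 1.0), 0.0),
        p_value=p,
        classification=cls,
        n_points=int(t.size),
        alpha=alpha,
    )
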