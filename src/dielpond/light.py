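"""Underwater light attenuation.

Downwelling photosynthetically active radiation (PAR) in a turbid pond decays
approximately exponentially with depth (Beer–Lambert law),

    E_d(z) = E_d(0) * exp(-K_d * z),

where ``E_d(z)`` is the irradiance at depth ``z`` (cm), ``E_d(0)`` the
irradiance just below the water surface, and ``K_d`` the diffuse attenuation
coefficient (cm^-1).  ``K_d`` is estimated by ordinary least squares on the
linearised form ``ln E_d(z) = ln E_d(0) - K_d * z``; an optional nonlinear
refit on the exponential form is available for heteroscedastic profiles.

Depths are in centimetres and ``K_d`` in cm^-1 throughout: the ponds this
package targets are 15–20 cm deep and attenuation is strong enough (order
0.3 cm^-1) that metre-based units would be unwieldy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, FitInfeasibleError, ValidationError

__all__ = [
    "IrradianceProfile",
    "KdEstimate",
    "fit_kd",
    "attenuate",
    "attenuation_depth",
]

#: Minimum number of positive-irradiance points required for a fit.
MIN_FIT_POINTS = 3


@dataclass(frozen=True)
class IrradianceProfile:
    """A depth-resolved downwelling PAR profile.

    Parameters
    ----------
    depth_cm
        Depths in cm, strictly increasing, first value 0 (the reading just
        below the water surface is the surface reference).
    e_par
        Downwelling PAR at each depth (µmol photons m⁻² s⁻¹).
    site_id, timestamp
        Provenance labels; not used in computation.
    """

    depth_cm: np.ndarray
    e_par: np.ndarray
    site_id: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth_cm", np.asarray(self.depth_cm, dtype=float))
        object.__setattr__(self, "e_par", np.asarray(self.e_par, dtype=float))
        self.validate()

    def validate(self) -> None:
        z, e = self.depth_cm, self.e_par
        if z.ndim != 1 or e.ndim != 1 or z.size != e.size:
            raise ValidationError("depth_cm and e_par must be 1-d arrays of equal length")
        if z.size and z[0] < 0:
            raise ValidationError("depths must be non-negative")
        if np.any(np.diff(z) <= 0):
            raise ValidationError("depths must be strictly increasing")

    def qc_positive(self) -> "IrradianceProfile":
        """Drop non-positive irradiance readings (with a warning)."""
        keep = self.e_par > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} non-positive irradiance reading(s) "
                f"from profile {self.site_id or '<unnamed>'}",
                stacklevel=2,
            )
        return IrradianceProfile(
            self.depth_cm[keep], self.e_par[keep], self.site_id, self.timestamp
        )


@dataclass(frozen=True)
class KdEstimate:
    """Result of a diffuse-attenuation-coefficient fit.

    ``kd`` is the slope of ``-ln E_d(z)`` versus ``z`` (cm^-1); ``se`` its
    standard error; ``r_squared`` the log-space coefficient of determination;
    ``e0`` the fitted subsurface irradiance ``exp(intercept)``.
    """

    kd: float
    se: float
    r_squared: float
    n_points: int
    e0: float
    method: str = "ols-log"

    def summary(self) -> str:
        return (
            f"K_dPAR = {self.kd:.4g} cm^-1 (SE {self.se:.2g}), "
            f"r^2 = {self.r_squared:.4f}, n = {self.n_points}, "
            f"E_d(0) = {self.e0:.4g}"
        )


def fit_kd(profile: IrradianceProfile, *, nonlinear: bool = False) -> KdEstimate:
    """Estimate the diffuse attenuation coefficient from a PAR profile.

    Fits ``ln E = ln E0 - K_d z`` by ordinary least squares after dropping
    non-positive readings.  With ``nonlinear=True`` the OLS solution seeds a
    nonlinear least-squares refit of the exponential form.

    Raises
    ------
    FitInfeasibleError
        If fewer than three positive-irradiance points remain.
    """
    clean = profile.qc_positive()
    z, e = clean.depth_cm, clean.e_par
    if z.size < MIN_FIT_POINTS:
        raise FitInfeasibleError(
            f"need at least {MIN_FIT_POINTS} positive-irradiance points, got {z.size}"
        )
    y = np.log(e)
    res = stats.linregress(z, y)
    kd = -res.slope
    se = res.stderr
    # Constant profiles make r undefined in linregress; a flat log profile is a
    # perfect zero-slope fit, so report r^2 = 1 when residual variation is nil.
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - (res.intercept + res.slope * z)) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    e0 = float(np.exp(res.intercept))

    if nonlinear:
        popt, pcov = optimize.curve_fit(
            lambda zz, e0_, kd_: e0_ * np.exp(-kd_ * zz), z, e, p0=[e0, kd]
        )
        e0, kd = float(popt[0]), float(popt[1])
        se = float(np.sqrt(pcov[1, 1]))
        fitted = popt[0] * np.exp(-popt[1] * z)
        ss_res_nl = float(np.sum((e - fitted) ** 2))
        ss_tot_nl = float(np.sum((e - e.mean()) ** 2))
        r2 = 1.0 if ss_tot_nl == 0.0 else 1.0 - ss_res_nl / ss_tot_nl
        return KdEstimate(kd, se, max(min(r2, 1.0), 0.0), int(z.size), e0, "nls-exp")

    return KdEstimate(float(kd), float(se), max(min(r2, 1.0), 0.0), int(z.size), e0)


def attenuate(e0: float, kd: float, z) -> np.ndarray | float:
    """Irradiance remaining at depth ``z``: ``e0 * exp(-kd * z)``.

    Monotone non-increasing in ``z``; all arguments must be non-negative.
    """
    z = np.asarray(z, dtype=float)
    if e0 < 0:
        raise DomainError("surface irradiance must be non-negative")
    if kd < 0:
        raise DomainError("attenuation coefficient must be non-negative")
    if np.any(z < 0):
        raise DomainError("depth must be non-negative")
    out = e0 * np.exp(-kd * z)
    return float(out) if out.ndim == 0 else out


def attenuation_depth(kd: float, retained_fraction: float) -> float:
    """Depth (cm) at which irradiance falls to ``retained_fraction`` of surface.

    Inverts the Beer–Lambert law: ``z = -ln(f) / kd`` for ``f`` in (0, 1].
    For example, the depth of 20% PAR attenuation is
    ``attenuation_depth(kd, 0.8)``.
    """
    if not (0 < retained_fraction <= 1):
        raise DomainError("retained_fraction must lie in (0, 1]")
    if kd <= 0:
        raise DomainError("attenuation coefficient must be positive")
    return float(-np.log(retained_fraction) / kd)


def fit_profiles(profiles: Sequence[IrradianceProfile], **kwargs) -> list[KdEstimate]:
    """Fit each profile in turn (convenience for tables of profiles)."""
    return [fit_kd(p, **kwargs) for p in profiles]
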