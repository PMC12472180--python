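"""Equilibrium solubility functions for CO2, CH4 and N2O.

All three gases use the standard oceanographic fit

    ln K = A1 + A2*(100/T) + A3*ln(T/100) + S*(B1 + B2*(T/100) + B3*(T/100)^2)

with T in kelvin and S the practical salinity, returning a Henry-type
solubility in mol L^-1 atm^-1 (dissolved concentration per unit partial
pressure).  Coefficient sets are the community-standard ones:

* CO2  — Weiss (1974), Mar. Chem. 2:203, K0 in mol L^-1 atm^-1.
* N2O  — Weiss & Price (1980), Mar. Chem. 8:347, K0 in mol L^-1 atm^-1.
* CH4  — Wiesenburg & Guinasso (1979), J. Chem. Eng. Data 24:356, Bunsen
  coefficient (L gas at STP per L water per atm), converted to
  mol L^-1 atm^-1 by dividing by the STP molar volume 22.414 L mol^-1.

Solubility decreases with temperature and with salinity (salting-out) over
the environmental range; inputs outside T in [-2, 40] degC or S in [0, 40]
are extrapolations and trigger a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DomainError

__all__ = ["equilibrium_solubility", "SUPPORTED_GASES", "MOLAR_VOLUME_STP_L"]

#: STP molar volume used to convert Bunsen coefficients (L mol^-1).
MOLAR_VOLUME_STP_L = 22.414

# (A1, A2, A3), (B1, B2, B3), bunsen?
_COEFFS = {
    "CO2": ((-58.0931, 90.5069, 22.2940), (0.027766, -0.025888, 0.0050578), False),
    "N2O": ((-62.7062, 97.3066, 24.1406), (-0.058420, 0.033193, -0.0051313), False),
    "CH4": ((-68.8862, 101.4956, 28.7314), (-0.076146, 0.043970, -0.0068672), True),
}

SUPPORTED_GASES = tuple(_COEFFS)

_T_RANGE = (-2.0, 40.0)
_S_RANGE = (0.0, 40.0)


def equilibrium_solubility(gas: str, temp_c: float, salinity: float) -> float:
    """Henry-type solubility of ``gas`` in mol L^-1 atm^-1 at (T, S).

    Used both to back-calculate dissolved concentrations from headspace
    measurements and to form the air-equilibrium reference concentration.
    """
    gas = gas.upper()
    if gas not in _COEFFS:
        raise DomainError(f"unsupported gas {gas!r}; expected one of {SUPPORTED_GASES}")
    if not (_T_RANGE[0] <= temp_c <= _T_RANGE[1]) or not (
        _S_RANGE[0] <= salinity <= _S_RANGE[1]
    ):
        warnings.warn(
            f"solubility of {gas} at T={temp_c} degC, S={salinity} is an "
            "extrapolation beyond the fitted range",
            stacklevel=2,
        )
    (a1, a2, a3), (b1, b2, b3), bunsen = _COEFFS[gas]
    t = (temp_c + 273.15) / 100.0
    ln_k = a1 + a2 / t + a3 * np.log(t) + salinity * (b1 + b2 * t + b3 * t * t)
    k = float(np.exp(ln_k))
    if bunsen:
        k /= MOLAR_VOLUME_STP_L
    return k
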