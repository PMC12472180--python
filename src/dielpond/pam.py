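"""PAM (pulse-amplitude-modulated) chlorophyll-a fluorescence indices.

Photophysiology of the benthic microbial mat is summarised with the standard
fluorometric quantities:

* effective quantum yield of PSII in the light-adapted state,
  ``Yield II = ΔF/Fm' = (Fm' - F) / Fm'``;
* maximal quantum yield after dark adaptation,
  ``Fv/Fm = (Fm - Fo) / Fm`` — the classic photoinhibition indicator;
* relative electron transport rate, ``rETR = Yield II × E-PAR`` (relative
  units; incident PAR, no absorptance factor).

`diel_summary` condenses a day of records into a midday-depression and an
afternoon-recovery fraction, quantifying the photoinhibition/recovery cycle.
Records where instrument noise produces F > Fm' (negative yields) are kept
but flagged ``qc_valid = False`` and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

__all__ = [
    "effective_quantum_yield",
    "max_quantum_yield",
    "retr",
    "compute_indices",
    "diel_summary",
    "DielPhotoSummary",
    "DEFAULT_NOON_WINDOW",
]

#: Default solar-noon window (decimal hours, local time) for midday statistics.
DEFAULT_NOON_WINDOW = (11.0, 15.0)


def effective_quantum_yield(f, fm_prime):
    """ΔF/Fm' = (Fm' − F)/Fm'.  Requires Fm' > 0; F > Fm' gives a negative
    value (flagged, not raised — see `compute_indices`)."""
    f = np.asarray(f, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    if np.any(fm_prime <= 0):
        raise DomainError("Fm' must be positive")
    if np.any(f < 0):
        raise DomainError("F must be non-negative")
    out = (fm_prime - f) / fm_prime
    return float(out) if out.ndim == 0 else out


def max_quantum_yield(fo, fm):
    """Fv/Fm = (Fm − Fo)/Fm from dark-adapted basal and maximal fluorescence."""
    fo = np.asarray(fo, dtype=float)
    fm = np.asarray(fm, dtype=float)
    if np.any(fm <= 0):
        raise DomainError("Fm must be positive")
    if np.any(fo < 0):
        raise DomainError("Fo must be non-negative")
    out = (fm - fo) / fm
    return float(out) if out.ndim == 0 else out


def retr(yield_ii, e_par):
    """Relative electron transport rate: Yield II × incident E-PAR."""
    yield_ii = np.asarray(yield_ii, dtype=float)
    e_par = np.asarray(e_par, dtype=float)
    if np.any(yield_ii < 0) or np.any(yield_ii > 1):
        raise DomainError("yield must lie in [0, 1]")
    if np.any(e_par < 0):
        raise DomainError("E-PAR must be non-negative")
    out = yield_ii * e_par
    return float(out) if out.ndim == 0 else out


def compute_indices(records: pd.DataFrame) -> pd.DataFrame:
    """Add yield_ii, fvfm, retr and qc_valid columns to a record table.

    Expected columns: ``time_h`` (decimal hours) or ``timestamp``, ``f``,
    ``fm_prime``, ``e_par`` and optionally ``fo``/``fm`` on dark-adapted rows
    (NaN elsewhere).  Rows with F > Fm' or Fo > Fm are retained with
    ``qc_valid = False``.
    """
    req = {"f", "fm_prime", "e_par"}
    missing = req - set(records.columns)
    if missing:
        raise ValidationError(f"record table lacks columns: {sorted(missing)}")
    df = records.copy()
    if np.any(df["fm_prime"] <= 0):
        raise DomainError("Fm' must be positive for all records")

    df["yield_ii"] = (df["fm_prime"] - df["f"]) / df["fm_prime"]
    qc = (df["f"] >= 0) & (df["f"] <= df["fm_prime"]) & (df["e_par"] >= 0)

    if {"fo", "fm"}.issubset(df.columns):
        dark = df["fo"].notna() & df["fm"].notna()
        if np.any(dark & (df["fm"] <= 0)):
            raise DomainError("Fm must be positive for dark-adapted records")
        df["fvfm"] = np.where(dark, (df["fm"] - df["fo"]) / df["fm"], np.nan)
        qc &= ~(dark & (df["fo"] > df["fm"]))
    else:
        df["fvfm"] = np.nan

    df["qc_valid"] = qc
    y = df["yield_ii"].clip(lower=0.0)
    df["retr"] = np.where(qc, y * df["e_par"], np.nan)
    return df


@dataclass(frozen=True)
class DielPhotoSummary:
    """Diel photoinhibition summary.

    midday_depression
        1 − min(Fv/Fm in the noon window) / max(Fv/Fm before the window);
        0 means no midday decline.
    recovery_fraction
        Last afternoon Fv/Fm divided by the pre-noon maximum; 1 means full
        recovery.
    """

    indices: pd.DataFrame = field(repr=False)
    midday_depression: float
    recovery_fraction: float
    fvfm_noon_min: float
    fvfm_morning_max: float
    noon_window: tuple[float, float]
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "midday_depression": self.midday_depression,
            "recovery_fraction": self.recovery_fraction,
            "fvfm_noon_min": self.fvfm_noon_min,
            "fvfm_morning_max": self.fvfm_morning_max,
            "noon_window": list(self.noon_window),
            "flags": list(self.flags),
        }


def _time_hours(df: pd.DataFrame) -> pd.Series:
    if "time_h" in df.columns:
        return df["time_h"].astype(float)
    if "timestamp" in df.columns:
        ts = pd.to_datetime(df["timestamp"])
        return ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    raise ValidationError("record table needs a time_h or timestamp column")


def diel_summary(
    records: pd.DataFrame,
    noon_window: tuple[float, float] = DEFAULT_NOON_WINDOW,
) -> DielPhotoSummary:
    """Summarise a day of PAM records into depression/recovery fractions.

    Requires at least three QC-valid timepoints spanning morning, the noon
    window and afternoon.  Uses Fv/Fm where dark-adapted readings exist;
    records flagged invalid by `compute_indices` are excluded.
    """
    lo, hi = noon_window
    if not lo < hi:
        raise ValidationError("noon window must be a non-empty interval")

    df = compute_indices(records)
    df = df.assign(_t=_time_hours(df)).sort_values("_t")
    valid = df[df["qc_valid"]]
    if len(valid) < 3:
        raise ValidationError("need at least 3 QC-valid timepoints for a diel summary")

    flags: list[str] = []
    series = valid.dropna(subset=["fvfm"])
    col = "fvfm"
    if series.empty:
        # No dark-adapted readings: fall back to Yield II, flagged.
        flags.append("fvfm-missing-used-yield_ii")
        series = valid
        col = "yield_ii"

    morning = series[series["_t"] < lo]
    noon = series[(series["_t"] >= lo) & (series["_t"] <= hi)]
    afternoon = series[series["_t"] > hi]
    if morning.empty or noon.empty or afternoon.empty:
        raise ValidationError(
            "records must span morning, the noon window, and afternoon"
        )

    morning_max = float(morning[col].max())
    noon_min = float(noon[col].min())
    depression = 1.0 - noon_min / morning_max
    recovery = float(afternoon.iloc[-1][col]) / morning_max

    return DielPhotoSummary(
        indices=df.drop(columns="_t"),
        midday_depression=depression,
        recovery_fraction=recovery,
        fvfm_noon_min=noon_min,
        fvfm_morning_max=morning_max,
        noon_window=(lo, hi),
        flags=tuple(flags),
    )
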