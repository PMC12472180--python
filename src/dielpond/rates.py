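"""Endpoint nutrient rates and inhibitor-based nitrification partitioning.

Dark endpoint incubations (duplicate 125 mL flasks, 5-6 h) give net rates of
change R = (final - initial) / duration in µM h^-1 for each inhibitor
treatment.  The difference design attributes nitrite rate components to
ammonia-oxidizing guilds by subtracting the uninhibited control:

    R_AOB   = R(azide + GC7) - R(control)     # GC7 suppresses archaea
    R_AOA   = R(azide + ATU) - R(control)     # ATU suppresses bacteria
    R_other = R(azide)       - R(control)     # azide blocks nitrite sinks

Components may be negative (net consumption); they are reported as-is.

Uncertainty convention: the per-treatment ``spread`` is the replicate SD for
n > 2, the half-range for duplicates (which equals the standard error of a
duplicate mean), and 0 (flagged) for single flasks.  Differences combine
operand spreads in quadrature into ``se`` and additionally report a 95%
expanded uncertainty ``u95`` using a Welch–Satterthwaite t multiplier — the
package's stated uncertainty for a partitioned rate, since a bare ±1 SE band
on a duplicate-based difference covers the truth barely half the time.

Inhibitor doses (ATU 84 mM, GC7 0.4 µM, azide 34 µM) are metadata only; they
never enter the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, MissingTreatmentError, ValidationError

__all__ = [
    "IncubationExperiment",
    "TreatmentRate",
    "TreatmentRates",
    "NitrificationPartition",
    "endpoint_rate",
    "treatment_rates",
    "partition_nitrification",
    "session_contrast",
    "CONTROL",
    "DEFAULT_EQUATIONS",
]

CONTROL = "CONTROL"

#: Component -> treatment whose control-difference estimates it.
DEFAULT_EQUATIONS = {
    "r_aob": "AZIDE_GC7",
    "r_aoa": "AZIDE_ATU",
    "r_other": "AZIDE",
}

KNOWN_TREATMENTS = ("CONTROL", "ATU", "GC7", "AZIDE", "AZIDE_GC7", "AZIDE_ATU")


def endpoint_rate(initial_um, final_um, duration_h):
    """Net rate of change (µM h^-1) from a single endpoint pair."""
    duration_h = np.asarray(duration_h, dtype=float)
    if np.any(duration_h <= 0):
        raise DomainError("incubation duration must be positive")
    out = (np.asarray(final_um, float) - np.asarray(initial_um, float)) / duration_h
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class IncubationExperiment:
    """Treatment-labelled initial/final nutrient concentrations.

    ``treatments`` maps a treatment label to a list of replicate
    ``(initial_um, final_um)`` pairs.  CONTROL must be present.
    """

    session: str
    analyte: str
    duration_h: float
    treatments: dict[str, list[tuple[float, float]]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValidationError("duration must be positive")
        if CONTROL not in self.treatments:
            raise ValidationError("CONTROL treatment is required")
        for label, reps in self.treatments.items():
            if len(reps) < 1:
                raise ValidationError(f"treatment {label!r} has no replicates")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IncubationExperiment":
        """Build from a tidy table with columns session, analyte, treatment,
        replicate, initial_um, final_um, duration_h (one experiment only)."""
        req = {"session", "analyte", "treatment", "initial_um", "final_um", "duration_h"}
        missing = req - set(df.columns)
        if missing:
            raise ValidationError(f"incubation table lacks columns: {sorted(missing)}")
        sessions = df["session"].unique()
        analytes = df["analyte"].unique()
        if len(sessions) != 1 or len(analytes) != 1:
            raise ValidationError("one experiment = one (session, analyte)")
        durations = df["duration_h"].unique()
        if len(durations) != 1:
            raise ValidationError("mixed durations within one experiment")
        treatments: dict[str, list[tuple[float, float]]] = {}
        for label, grp in df.groupby("treatment"):
            treatments[str(label)] = list(
                zip(grp["initial_um"].astype(float), grp["final_um"].astype(float))
            )
        return cls(
            session=str(sessions[0]),
            analyte=str(analytes[0]),
            duration_h=float(durations[0]),
            treatments=treatments,
        )


@dataclass(frozen=True)
class TreatmentRate:
    """Replicate-mean rate for one treatment.

    ``spread``: SD (n>2), half-range (n=2, flagged 'half-range'), or 0
    (n=1, flagged 'single-replicate').
    """

    rate: float
    spread: float
    n: int
    spread_kind: str


@dataclass(frozen=True)
class TreatmentRates:
    session: str
    analyte: str
    duration_h: float
    rates: dict[str, TreatmentRate]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "treatment": k,
                    "rate_um_h": v.rate,
                    "spread": v.spread,
                    "n": v.n,
                    "spread_kind": v.spread_kind,
                }
                for k, v in self.rates.items()
            ]
        )


def treatment_rates(experiment: IncubationExperiment) -> TreatmentRates:
    """Per-treatment mean endpoint rates with replicate spread."""
    out: dict[str, TreatmentRate] = {}
    for label, reps in experiment.treatments.items():
        r = np.array(
            [endpoint_rate(i, f, experiment.duration_h) for i, f in reps], dtype=float
        )
        n = r.size
        if n == 1:
            spread, kind = 0.0, "single-replicate"
        elif n == 2:
            spread, kind = float(abs(r[1] - r[0]) / 2.0), "half-range"
        else:
            spread, kind = float(np.std(r, ddof=1)), "sd"
        out[label] = TreatmentRate(float(r.mean()), spread, int(n), kind)
    return TreatmentRates(experiment.session, experiment.analyte, experiment.duration_h, out)


@dataclass(frozen=True)
class NitrificationPartition:
    """AOB / AOA / other-process contributions to the net nitrite rate.

    Each component carries a quadrature standard error ``se`` and a 95%
    expanded uncertainty ``u95`` (Welch t); values may be negative.
    """

    session: str
    r_aob: float
    r_aoa: float
    r_other: float
    se: dict[str, float]
    u95: dict[str, float]
    dof: dict[str, float]

    def component(self, name: str) -> tuple[float, float, float]:
        """(value, se, u95) for 'r_aob' | 'r_aoa' | 'r_other'."""
        return getattr(self, name), self.se[name], self.u95[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("r_aob", "r_aoa", "r_other"):
            rows.append(
                {
                    "component": name,
                    "rate_um_h": getattr(self, name),
                    "se": self.se[name],
                    "u95": self.u95[name],
                    "session": self.session,
                }
            )
        return pd.DataFrame(rows)


def _difference_uncertainty(
    a: TreatmentRate, b: TreatmentRate
) -> tuple[float, float, float]:
    """Quadrature SE, Welch df and 95% expanded uncertainty for a - b."""
    s1, s2 = a.spread, b.spread
    se = float(np.hypot(s1, s2))
    d1, d2 = max(a.n - 1, 1), max(b.n - 1, 1)
    denom = s1**4 / d1 + s2**4 / d2
    if se == 0.0 or denom == 0.0:
        return se, float(min(d1, d2)), 0.0 if se == 0.0 else se
    df = (s1**2 + s2**2) ** 2 / denom
    t_mult = float(sps.t.ppf(0.975, df))
    return se, float(df), t_mult * se


def partition_nitrification(
    rates: TreatmentRates,
    equations: dict[str, str] | None = None,
) -> NitrificationPartition:
    """Apply the control-difference equations to treatment rates.

    ``equations`` maps each component to the treatment whose difference from
    CONTROL estimates it (default: AZIDE_GC7 -> AOB, AZIDE_ATU -> AOA,
    AZIDE -> other).  Raises `MissingTreatmentError` naming any absent label.
    """
    eqs = dict(DEFAULT_EQUATIONS if equations is None else equations)
    if CONTROL not in rates.rates:
        raise MissingTreatmentError(CONTROL)
    ctrl = rates.rates[CONTROL]
    values: dict[str, float] = {}
    se: dict[str, float] = {}
    u95: dict[str, float] = {}
    dof: dict[str, float] = {}
    for comp, label in eqs.items():
        if label not in rates.rates:
            raise MissingTreatmentError(label)
        tr = rates.rates[label]
        values[comp] = tr.rate - ctrl.rate
        se[comp], dof[comp], u95[comp] = _difference_uncertainty(tr, ctrl)
    return NitrificationPartition(
        session=rates.session,
        r_aob=values["r_aob"],
        r_aoa=values["r_aoa"],
        r_other=values["r_other"],
        se=se,
        u95=u95,
        dof=dof,
    )


def session_contrast(morning, afternoon) -> pd.DataFrame:
    """Morning-minus-afternoon table for partitions or treatment rates.

    Accepts two `NitrificationPartition` or two `TreatmentRates` objects.
    Returns a frame with the per-quantity difference, combined (quadrature)
    SE and a ``morning_higher`` flag.
    """
    if morning is None or afternoon is None:
        raise ValidationError("both sessions are required for a contrast")

    rows = []
    if isinstance(morning, NitrificationPartition):
        if not isinstance(afternoon, NitrificationPartition):
            raise ValidationError("session objects must be of the same kind")
        for comp in ("r_aob", "r_aoa", "r_other"):
            m, m_se, _ = morning.component(comp)
            a, a_se, _ = afternoon.component(comp)
            rows.append(
                {
                    "quantity": comp,
                    "morning": m,
                    "afternoon": a,
                    "difference": m - a,
                    "se": float(np.hypot(m_se, a_se)),
                    "morning_higher": m > a,
                }
            )
    elif isinstance(morning, TreatmentRates):
        if not isinstance(afternoon, TreatmentRates):
            raise ValidationError("session objects must be of the same kind")
        common = sorted(set(morning.rates) & set(afternoon.rates))
        if not common:
            raise ValidationError("sessions share no treatments")
        for label in common:
            m, a = morning.rates[label], afternoon.rates[label]
            rows.append(
                {
                    "quantity": label,
                    "morning": m.rate,
                    "afternoon": a.rate,
                    "difference": m.rate - a.rate,
                    "se": float(np.hypot(m.spread, a.spread)),
                    "morning_higher": m.rate > a.rate,
                }
            )
    else:
        raise ValidationError("unsupported session object type")
    return pd.DataFrame(rows)
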