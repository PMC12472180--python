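"""CSV readers and schema validators for every stage input.

Each reader returns the stage's in-memory objects; each ``validate_*``
function returns a list of row-level violation records
``{"table", "code", "row", "message"}`` without raising, so a whole bundle
can be audited in one pass (`validate_bundle`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gas import ChamberSeries, GasSample
from .light import IrradianceProfile
from .rates import IncubationExperiment

__all__ = [
    "read_profiles",
    "read_pam",
    "read_gas_samples",
    "read_chamber_series",
    "read_incubations",
    "validate_profiles",
    "validate_pam",
    "validate_gas_samples",
    "validate_chamber",
    "validate_incubations",
    "validate_bundle",
]


def _require(df: pd.DataFrame, cols: set[str], table: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValidationError(f"{table}: missing columns {sorted(missing)}")


# ---------------------------------------------------------------- profiles

PROFILE_COLS = {"depth_cm", "e_par"}


def read_profiles(path) -> list[IrradianceProfile]:
    """Read depth-irradiance profiles; rows grouped by (site_id, timestamp)."""
    df = pd.read_csv(path)
    _require(df, PROFILE_COLS, "profiles")
    for col in ("site_id", "timestamp"):
        if col not in df.columns:
            df[col] = ""
    out = []
    for (site, ts), grp in df.groupby(["site_id", "timestamp"], sort=False, dropna=False):
        grp = grp.sort_values("depth_cm")
        out.append(
            IrradianceProfile(
                grp["depth_cm"].to_numpy(float),
                grp["e_par"].to_numpy(float),
                site_id=str(site),
                timestamp=str(ts),
            )
        )
    return out


def validate_profiles(df: pd.DataFrame) -> list[dict]:
    violations = []
    missing = PROFILE_COLS - set(df.columns)
    if missing:
        return [{"table": "profiles", "code": "missing-columns", "row": None,
                 "message": str(sorted(missing))}]
    keys = [c for c in ("site_id", "timestamp") if c in df.columns]
    groups = df.groupby(keys, sort=False, dropna=False) if keys else [((), df)]
    for key, grp in groups:
        z = grp["depth_cm"].to_numpy(float)
        if np.any(np.diff(z) <= 0):
            violations.append(
                {"table": "profiles", "code": "depths-not-strictly-increasing",
                 "row": key, "message": "duplicate or non-increasing depths"}
            )
        if (grp["e_par"] <= 0).any():
            violations.append(
                {"table": "profiles", "code": "nonpositive-irradiance", "row": key,
                 "message": f"{int((grp['e_par'] <= 0).sum())} rows"}
            )
        if (grp["e_par"] > 0).sum() < 3:
            violations.append(
                {"table": "profiles", "code": "too-few-points", "row": key,
                 "message": "fewer than 3 positive-irradiance points"}
            )
    return violations


# ---------------------------------------------------------------- PAM

PAM_COLS = {"f", "fm_prime", "e_par"}


def read_pam(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PAM_COLS, "pam")
    return df


def validate_pam(df: pd.DataFrame) -> list[dict]:
    violations = []
    missing = PAM_COLS - set(df.columns)
    if missing:
        return [{"table": "pam", "code": "missing-columns", "row": None,
                 "message": str(sorted(missing))}]
    for idx, row in df.iterrows():
        if row["fm_prime"] <= 0:
            violations.append({"table": "pam", "code": "nonpositive-fm-prime",
                               "row": int(idx), "message": ""})
        elif row["f"] > row["fm_prime"]:
            violations.append({"table": "pam", "code": "f-exceeds-fm-prime",
                               "row": int(idx), "message": "QC flag"})
        if "fm" in df.columns and pd.notna(row.get("fm")) and pd.notna(row.get("fo")):
            if row["fm"] <= 0:
                violations.append({"table": "pam", "code": "nonpositive-fm",
                                   "row": int(idx), "message": ""})
            elif row["fo"] > row["fm"]:
                violations.append({"table": "pam", "code": "fo-exceeds-fm",
                                   "row": int(idx), "message": "QC flag"})
    return violations


# ---------------------------------------------------------------- gas vials

GAS_COLS = {"gas", "headspace_ppm", "vial_volume_ml", "headspace_volume_ml",
            "temp_c", "salinity"}


def read_gas_samples(path) -> list[GasSample]:
    df = pd.read_csv(path)
    _require(df, GAS_COLS, "gas_vials")
    out = []
    for _, row in df.iterrows():
        out.append(
            GasSample(
                gas=str(row["gas"]),
                headspace_ppm=float(row["headspace_ppm"]),
                vial_volume_ml=float(row["vial_volume_ml"]),
                headspace_volume_ml=float(row["headspace_volume_ml"]),
                temp_c=float(row["temp_c"]),
                salinity=float(row["salinity"]),
                pressure_atm=float(row.get("pressure_atm", 0.64)),
                timestamp=str(row.get("timestamp", "")),
                replicate=str(row.get("replicate", "")),
            )
        )
    return out


def validate_gas_samples(df: pd.DataFrame) -> list[dict]:
    violations = []
    missing = GAS_COLS - set(df.columns)
    if missing:
        return [{"table": "gas_vials", "code": "missing-columns", "row": None,
                 "message": str(sorted(missing))}]
    for idx, row in df.iterrows():
        if not (0 < row["headspace_volume_ml"] < row["vial_volume_ml"]):
            violations.append({"table": "gas_vials", "code": "volume-invariant",
                               "row": int(idx),
                               "message": "need 0 < headspace < vial volume"})
        if row["headspace_ppm"] < 0:
            violations.append({"table": "gas_vials", "code": "negative-mole-fraction",
                               "row": int(idx), "message": ""})
        if "pressure_atm" in df.columns and row["pressure_atm"] <= 0:
            violations.append({"table": "gas_vials", "code": "nonpositive-pressure",
                               "row": int(idx), "message": ""})
    return violations


# ---------------------------------------------------------------- chamber

CHAMBER_COLS = {"gas", "time_min", "ppm"}


def read_chamber_series(
    path,
    chamber_volume_l: float | None = None,
    chamber_area_m2: float | None = None,
    temp_c: float | None = None,
    pressure_atm: float | None = None,
) -> dict[str, ChamberSeries]:
    """Read chamber time series, one `ChamberSeries` per gas.

    Geometry/conditions come from columns when present, else from the
    keyword overrides (config values).
    """
    df = pd.read_csv(path)
    _require(df, CHAMBER_COLS, "chamber")
    out = {}
    for gas, grp in df.groupby("gas", sort=False):
        grp = grp.sort_values("time_min")

        def pick(col, override, default=None):
            if override is not None:
                return override
            if col in grp.columns:
                return float(grp[col].iloc[0])
            if default is not None:
                return default
            raise ValidationError(f"chamber: no {col} column and no override given")

        out[str(gas)] = ChamberSeries(
            gas=str(gas),
            times_min=grp["time_min"].to_numpy(float),
            mole_fraction_ppm=grp["ppm"].to_numpy(float),
            chamber_volume_l=pick("chamber_volume_l", chamber_volume_l),
            chamber_area_m2=pick("chamber_area_m2", chamber_area_m2),
            temp_c=pick("temp_c", temp_c),
            pressure_atm=pick("pressure_atm", pressure_atm, 0.64),
        )
    return out


def validate_chamber(df: pd.DataFrame) -> list[dict]:
    violations = []
    missing = CHAMBER_COLS - set(df.columns)
    if missing:
        return [{"table": "chamber", "code": "missing-columns", "row": None,
                 "message": str(sorted(missing))}]
    for gas, grp in df.groupby("gas", sort=False):
        t = grp.sort_values("time_min")["time_min"].to_numpy(float)
        if t.size < 3:
            violations.append({"table": "chamber", "code": "too-few-points",
                               "row": str(gas), "message": f"{t.size} points"})
        if np.any(np.diff(t) <= 0):
            violations.append({"table": "chamber", "code": "times-not-increasing",
                               "row": str(gas), "message": "duplicate times"})
    return violations


# ---------------------------------------------------------------- incubations

INC_COLS = {"session", "analyte", "treatment", "initial_um", "final_um", "duration_h"}


def read_incubations(path) -> dict[tuple[str, str], IncubationExperiment]:
    """Read incubations keyed by (session, analyte)."""
    df = pd.read_csv(path)
    _require(df, INC_COLS, "incubations")
    out = {}
    for (session, analyte), grp in df.groupby(["session", "analyte"], sort=False):
        out[(str(session), str(analyte))] = IncubationExperiment.from_dataframe(grp)
    return out


def validate_incubations(df: pd.DataFrame) -> list[dict]:
    violations = []
    missing = INC_COLS - set(df.columns)
    if missing:
        return [{"table": "incubations", "code": "missing-columns", "row": None,
                 "message": str(sorted(missing))}]
    if (df["duration_h"] <= 0).any():
        violations.append({"table": "incubations", "code": "nonpositive-duration",
                           "row": None, "message": ""})
    for (session, analyte), grp in df.groupby(["session", "analyte"], sort=False):
        if "CONTROL" not in set(grp["treatment"]):
            violations.append(
                {"table": "incubations", "code": "missing-control",
                 "row": f"{session}/{analyte}", "message": "CONTROL absent"}
            )
    return violations


# ---------------------------------------------------------------- bundle

_VALIDATORS = {
    "profiles.csv": validate_profiles,
    "pam.csv": validate_pam,
    "gas_vials.csv": validate_gas_samples,
    "chamber.csv": validate_chamber,
    "incubations.csv": validate_incubations,
}


def validate_bundle(directory) -> list[dict]:
    """Validate every recognised table in a bundle directory."""
    directory = Path(directory)
    violations: list[dict] = []
    for name, fn in _VALIDATORS.items():
        path = directory / name
        if not path.exists():
            continue
        try:
            violations.extend(fn(pd.read_csv(path)))
        except Exception as exc:  # unreadable file is itself a violation
            violations.append({"table": name, "code": "unreadable", "row": None,
                               "message": str(exc)})
    return violations
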