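"""Pipeline orchestration: light -> PAM -> gases -> rates -> stats.

`run_pipeline` executes every stage on a `RunConfig` pointing at CSV inputs
and returns a single JSON-serialisable report; `run_on_bundle` does the same
for an in-memory synthetic bundle.  The orchestrator contains no science —
every number in the report is produced by a stage function — and a stage
failure marks that stage (and its dependents) without aborting the rest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gas as gasmod
from . import io as iomod
from . import light as lightmod
from . import pam as pammod
from . import rates as ratesmod
from . import stats as statsmod
from .errors import DielPondError
from .synth import SyntheticBundle

__all__ = ["RunConfig", "run_pipeline", "run_on_bundle", "validate_inputs"]


@dataclass
class RunConfig:
    """Paths and settings for one pipeline run."""

    profiles: str | None = None
    pam: str | None = None
    gas_vials: str | None = None
    chamber: str | None = None
    incubations: str | None = None
    out_dir: str = "dielpond_out"
    pressure_atm: float = gasmod.DEFAULT_PRESSURE_ATM
    atmosphere_ppm: dict = field(
        default_factory=lambda: dict(gasmod.DEFAULT_ATMOSPHERE_PPM)
    )
    chamber_volume_l: float | None = None
    chamber_area_m2: float | None = None
    chamber_temp_c: float | None = None
    alpha: float = 0.05
    alpha_assumption: float = 0.05
    noon_window: tuple[float, float] = pammod.DEFAULT_NOON_WINDOW
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DielPondError(f"unknown config keys: {sorted(unknown)}")
        if "noon_window" in raw:
            raw["noon_window"] = tuple(raw["noon_window"])
        return cls(**raw)


def validate_inputs(config: RunConfig) -> list[dict]:
    """Schema-check every table the config references."""
    checks = [
        ("profiles", config.profiles, iomod.validate_profiles),
        ("pam", config.pam, iomod.validate_pam),
        ("gas_vials", config.gas_vials, iomod.validate_gas_samples),
        ("chamber", config.chamber, iomod.validate_chamber),
        ("incubations", config.incubations, iomod.validate_incubations),
    ]
    violations: list[dict] = []
    for name, path, fn in checks:
        if path is None:
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            violations.append({"table": name, "code": "unreadable", "row": None,
                               "message": str(exc)})
            continue
        violations.extend(fn(df))
    return violations


def _stage(report: dict, name: str, fn):
    """Run one stage, capturing failure without aborting the pipeline."""
    try:
        report[name] = {"status": "ok", "result": fn()}
    except FileNotFoundError as exc:
        report[name] = {"status": "skipped", "reason": str(exc)}
    except Exception as exc:
        report[name] = {"status": "failed", "reason": f"{type(exc).__name__}: {exc}"}


def _light_stage(profiles):
    ests = [lightmod.fit_kd(p) for p in profiles]
    kd_mean = float(np.mean([e.kd for e in ests]))
    return {
        "kd_mean_cm1": kd_mean,
        "depth_20pct_attenuation_cm": lightmod.attenuation_depth(kd_mean, 0.8),
        "fits": [
            {"kd": e.kd, "se": e.se, "r_squared": e.r_squared, "n_points": e.n_points}
            for e in ests
        ],
    }


def _pam_stage(records, noon_window):
    summary = pammod.diel_summary(records, noon_window)
    idx = summary.indices
    valid = idx[idx["qc_valid"]]
    return {
        **summary.to_dict(),
        "yield_ii_min": float(valid["yield_ii"].min()),
        "retr_max": float(valid["retr"].max()),
        "n_records": int(len(idx)),
    }


def _gas_dissolved_stage(samples, atmosphere_ppm):
    rows = []
    for s in samples:
        r = gasmod.dissolved_gas_result(s, atmosphere_ppm.get(s.gas.upper()))
        rows.append(
            {
                "gas": r.gas,
                "timestamp": r.timestamp,
                "replicate": r.replicate,
                "concentration": r.concentration,
                "unit": r.unit,
                "saturation_pct": r.saturation_pct,
                "status": r.status,
            }
        )
    df = pd.DataFrame(rows)
    by_gas = {}
    for gas, grp in df.groupby("gas"):
        mean_sat = float(grp["saturation_pct"].mean())
        by_gas[gas] = {
            "mean_concentration": float(grp["concentration"].mean()),
            "unit": grp["unit"].iloc[0],
            "mean_saturation_pct": mean_sat,
            "status": (
                "supersaturated" if mean_sat > 100
                else "subsaturated" if mean_sat < 100 else "equilibrium"
            ),
        }
    return {"samples": rows, "by_gas": by_gas}


def _gas_flux_stage(chambers, alpha):
    out = {}
    for gas, series in chambers.items():
        f = gasmod.chamber_flux(series, alpha=alpha)
        out[gas] = {
            "flux_umol_m2_h": f.flux,
            "flux_se": f.flux_se,
            "slope_ppm_per_min": f.slope_ppm_per_min,
            "r_squared": f.r_squared,
            "p_value": f.p_value,
            "classification": f.classification,
        }
    return out


def _rates_stage(experiments):
    """experiments: dict[(session, analyte)] -> IncubationExperiment."""
    out: dict = {"treatment_rates": {}, "partitions": {}, "session_contrast": None}
    partitions = {}
    for (session, analyte), exp in experiments.items():
        tr = ratesmod.treatment_rates(exp)
        out["treatment_rates"][f"{session}/{analyte}"] = tr.to_frame().to_dict("records")
        if analyte == "nitrite":
            try:
                part = ratesmod.partition_nitrification(tr)
            except DielPondError:
                continue
            partitions[session] = part
            out["partitions"][session] = part.to_frame().to_dict("records")
    if {"morning", "afternoon"} <= set(partitions):
        contrast = ratesmod.session_contrast(
            partitions["morning"], partitions["afternoon"]
        )
        out["session_contrast"] = contrast.to_dict("records")
    return out


def _stats_stage(experiments, alpha, alpha_assumption):
    """Morning-vs-afternoon comparison of replicate endpoint rates."""
    rows = []
    by_analyte: dict[str, list[tuple[str, float]]] = {}
    for (session, analyte), exp in experiments.items():
        for i0, f1 in exp.treatments.get(ratesmod.CONTROL, []):
            by_analyte.setdefault(analyte, []).append(
                (session, ratesmod.endpoint_rate(i0, f1, exp.duration_h))
            )
    for analyte, pairs in by_analyte.items():
        groups = np.array([s for s, _ in pairs])
        values = np.array([v for _, v in pairs])
        if len(set(groups)) < 2 or min((groups == g).sum() for g in set(groups)) < 2:
            continue
        cmp = statsmod.compare_groups(
            values, groups, alpha=alpha, alpha_assumption=alpha_assumption,
            variable=analyte,
        )
        rows.append(cmp.to_dict())
    return {"comparisons": rows}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on the configured CSV inputs and return the report."""
    report: dict = {"config": dataclasses.asdict(config), "validation": None}
    report["validation"] = validate_inputs(config)

    if config.profiles:
        _stage(report, "light", lambda: _light_stage(iomod.read_profiles(config.profiles)))
    else:
        report["light"] = {"status": "skipped", "reason": "no profiles input"}

    if config.pam:
        _stage(
            report, "pam",
            lambda: _pam_stage(iomod.read_pam(config.pam), config.noon_window),
        )
    else:
        report["pam"] = {"status": "skipped", "reason": "no pam input"}

    if config.gas_vials:
        _stage(
            report, "gas_dissolved",
            lambda: _gas_dissolved_stage(
                iomod.read_gas_samples(config.gas_vials), config.atmosphere_ppm
            ),
        )
    else:
        report["gas_dissolved"] = {"status": "skipped", "reason": "no gas_vials input"}

    if config.chamber:
        _stage(
            report, "gas_flux",
            lambda: _gas_flux_stage(
                iomod.read_chamber_series(
                    config.chamber,
                    chamber_volume_l=config.chamber_volume_l,
                    chamber_area_m2=config.chamber_area_m2,
                    temp_c=config.chamber_temp_c,
                    pressure_atm=config.pressure_atm,
                ),
                config.alpha,
            ),
        )
    else:
        report["gas_flux"] = {"status": "skipped", "reason": "no chamber input"}

    if config.incubations:
        experiments = None
        try:
            experiments = iomod.read_incubations(config.incubations)
        except Exception as exc:
            report["rates"] = {"status": "failed", "reason": str(exc)}
            report["stats"] = {"status": "skipped", "reason": "rates input unreadable"}
        if experiments is not None:
            _stage(report, "rates", lambda: _rates_stage(experiments))
            _stage(
                report, "stats",
                lambda: _stats_stage(experiments, config.alpha, config.alpha_assumption),
            )
    else:
        report["rates"] = {"status": "skipped", "reason": "no incubations input"}
        report["stats"] = {"status": "skipped", "reason": "no incubations input"}

    return report


def run_on_bundle(bundle: SyntheticBundle, config: RunConfig | None = None) -> dict:
    """Run all stages directly on an in-memory synthetic bundle."""
    cfg = config or RunConfig()
    report: dict = {"validation": []}
    _stage(report, "light", lambda: _light_stage(bundle.profiles))
    _stage(report, "pam", lambda: _pam_stage(bundle.pam, cfg.noon_window))
    samples = [
        gasmod.GasSample(
            gas=row["gas"],
            headspace_ppm=row["headspace_ppm"],
            vial_volume_ml=row["vial_volume_ml"],
            headspace_volume_ml=row["headspace_volume_ml"],
            temp_c=row["temp_c"],
            salinity=row["salinity"],
            pressure_atm=row["pressure_atm"],
            timestamp=row["timestamp"],
            replicate=row["replicate"],
        )
        for _, row in bundle.vials.iterrows()
    ]
    _stage(
        report, "gas_dissolved",
        lambda: _gas_dissolved_stage(samples, bundle.truth.gas.atmosphere_ppm),
    )
    _stage(report, "gas_flux", lambda: _gas_flux_stage(bundle.chambers, cfg.alpha))
    experiments = {(s, e.analyte): e for s, e in bundle.incubations.items()}
    _stage(report, "rates", lambda: _rates_stage(experiments))
    _stage(
        report, "stats",
        lambda: _stats_stage(experiments, cfg.alpha, cfg.alpha_assumption),
    )
    return report


def write_report(report: dict, out_dir) -> Path:
    """Write the JSON report (and return its path)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "diel_report.json"
    path.write_text(json.dumps(report, indent=2, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
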