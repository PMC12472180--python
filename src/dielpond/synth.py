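"""Seeded synthetic diel data with known ground truth.

Emulates one diel cycle of a shallow (15–20 cm) high-altitude peatland pond:

* a unimodal (half-sine) radiation day peaking near solar noon, with an
  air-temperature sinusoid lagging the sun and a wind step-ramp at noon;
* PAM fluorescence traces whose effective quantum yield dips linearly with
  irradiance (photoinhibition coupling) and whose dark-adapted Fv/Fm shows a
  configurable midday depression and afternoon recovery;
* dissolved-gas fields as diel sinusoids around configured means,
  forward-partitioned into headspace vial observations, plus linear-plus-
  noise floating-chamber series;
* endpoint incubations whose per-treatment net nitrite rates are composed
  from true (AOB, AOA, other) components through an inhibitor-efficacy
  ("reveal") matrix — ideal by default, so the control-difference equations
  recover the truth exactly at zero noise.

Default magnitudes follow the observed study conditions: PAR peak
1100 µmol m⁻² s⁻¹, UVA 165 / UVB 58 W m⁻², air temperature −5→18 °C, wind
1→6 m s⁻¹, K_d 0.32 cm⁻¹, midday Fv/Fm dipping from 0.80 to 0.75, mean
dissolved CO₂/CH₄/N₂O of 23.4 µM / 163.1 nM / 7.3 nM, and morning
nitrification above afternoon.  Noise magnitudes are assumptions (the field
campaign reports none) and are recorded in the truth object.

Reproducibility: one `numpy.random.SeedSequence` per bundle, spawned in a
fixed documented order (forcing, pam, gas, chamber, incubation-morning,
incubation-afternoon); identical seed + parameters give bit-identical
bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .gas import (
    DEFAULT_ATMOSPHERE_PPM,
    DEFAULT_PRESSURE_ATM,
    ChamberSeries,
    partition_to_headspace,
)
from .light import IrradianceProfile, attenuate
from .rates import CONTROL, IncubationExperiment

__all__ = [
    "ForcingTruth",
    "PhotoTruth",
    "GasTruth",
    "IncubationSessionTruth",
    "IncubationTruth",
    "SyntheticTruth",
    "SyntheticBundle",
    "gen_forcing",
    "gen_pam_trace",
    "gen_profiles",
    "gen_gas_field",
    "gen_incubation",
    "make_bundle",
]


@dataclass(frozen=True)
class ForcingTruth:
    """Diel radiation / temperature / wind forcing parameters."""

    peak_par: float = 1100.0  # µmol photons m^-2 s^-1
    peak_uva: float = 165.0  # W m^-2
    peak_uvb: float = 58.0  # W m^-2
    sunrise_h: float = 7.0
    sunset_h: float = 19.0
    temp_min_c: float = -5.0
    temp_max_c: float = 18.0
    temp_peak_h: float = 14.0  # lag of the temperature maximum behind noon
    wind_low_ms: float = 1.0
    wind_high_ms: float = 6.0
    wind_ramp_h: tuple[float, float] = (11.5, 12.5)
    timestep_min: float = 10.0
    noise_sigma: float = 0.01  # multiplicative lognormal sigma on radiation


@dataclass(frozen=True)
class PhotoTruth:
    """Photophysiology parameters of the mat."""

    fvfm_baseline: float = 0.80
    midday_depression: float = 0.0625  # 0.80 -> 0.75 at the midday minimum
    recovery_fraction: float = 1.0  # afternoon Fv/Fm relative to morning max
    yield_baseline: float = 0.75
    coupling: float = 0.2  # fractional yield loss at E = peak PAR
    fm_scale: float = 1000.0  # instrument-unit scale of Fm'
    depression_center_h: float = 13.0
    depression_width_h: float = 2.5
    sample_every_h: float = 2.0
    noise_sigma: float = 0.005  # additive Gaussian on yields


@dataclass(frozen=True)
class GasTruth:
    """Dissolved-gas field and chamber-deployment parameters."""

    mean_mol_l: dict[str, float] = field(
        default_factory=lambda: {"CO2": 23.4e-6, "CH4": 163.1e-9, "N2O": 7.3e-9}
    )
    rel_amplitude: float = 0.10
    # afternoon CH4 build-up; CO2 and N2O highest in the morning
    phase_peak_h: dict[str, float] = field(
        default_factory=lambda: {"CO2": 7.5, "CH4": 15.5, "N2O": 7.5}
    )
    sample_hours: tuple[float, ...] = (7.5, 11.5, 15.5)
    n_replicates: int = 3
    water_temp_c: float = 10.0
    salinity: float = 1.0
    pressure_atm: float = DEFAULT_PRESSURE_ATM
    atmosphere_ppm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATMOSPHERE_PPM)
    )
    vial_volume_ml: float = 20.0
    headspace_volume_ml: float = 5.0
    noise_rel: float = 0.01  # multiplicative noise on dissolved concentration
    # chamber deployment (afternoon, 20-min sampling)
    chamber_slopes_ppm_min: dict[str, float] = field(
        default_factory=lambda: {"CO2": -0.20, "CH4": 0.006, "N2O": 0.0}
    )
    chamber_noise_ppm: dict[str, float] = field(
        default_factory=lambda: {"CO2": 1.0, "CH4": 0.01, "N2O": 0.002}
    )
    chamber_times_min: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0)
    chamber_volume_l: float = 20.0
    chamber_area_m2: float = 0.25
    chamber_temp_c: float = 15.0


@dataclass(frozen=True)
class IncubationSessionTruth:
    """True rate components (µM h^-1) for one session."""

    control_rate: float
    r_aob: float
    r_aoa: float
    r_other: float


@dataclass(frozen=True)
class IncubationTruth:
    """Endpoint incubation design, true rates, and inhibitor efficacies."""

    morning: IncubationSessionTruth = IncubationSessionTruth(0.30, 0.25, 0.15, -0.05)
    afternoon: IncubationSessionTruth = IncubationSessionTruth(0.10, 0.05, 0.08, -0.02)
    duration_h: float = 5.5
    initial_um: float = 0.10
    noise_sigma_um: float = 0.05  # Gaussian SD on final concentrations
    n_replicates: int = 2
    # inhibitor efficacies in [0, 1]; ideal defaults
    e_azide: float = 1.0  # azide fully blocks nitrite sinks
    e_atu_aob: float = 1.0  # ATU fully suppresses AOB
    e_gc7_aoa: float = 1.0  # GC7 fully suppresses AOA
    e_atu_aoa: float = 0.0  # ATU's partial archaeal cross-inhibition
    # metadata only; never used in computation
    doses: dict[str, str] = field(
        default_factory=lambda: {"ATU": "84 mM", "GC7": "0.4 uM", "AZIDE": "34 uM"}
    )

    def reveal_matrix(self) -> dict[str, tuple[float, float, float]]:
        """Treatment -> (aob, aoa, other) coefficients.

        Each inhibitor combination exposes one rate component on top of the
        control baseline; the efficacy parameters scale or leak the exposed
        fractions (e.g. ATU cross-inhibition of archaea shrinks the AOA
        signal of the AZIDE_ATU flasks).  With ideal efficacies this is the
        identity design the difference equations assume.
        """
        for name in ("e_azide", "e_atu_aob", "e_gc7_aoa", "e_atu_aoa"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        ez = self.e_azide
        return {
            CONTROL: (0.0, 0.0, 0.0),
            "AZIDE": (0.0, 0.0, ez),
            "AZIDE_GC7": (ez, ez * (1.0 - self.e_gc7_aoa), 0.0),
            "AZIDE_ATU": (ez * (1.0 - self.e_atu_aob), ez * (1.0 - self.e_atu_aoa), 0.0),
        }


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one synthetic bundle."""

    seed: int = 0
    kd_true: float = 0.32  # cm^-1
    profile_depths_cm: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    profile_noise_sigma: float = 0.0  # multiplicative lognormal on irradiance
    forcing: ForcingTruth = ForcingTruth()
    photo: PhotoTruth = PhotoTruth()
    gas: GasTruth = GasTruth()
    incubation: IncubationTruth = IncubationTruth()

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        d = dataclasses.asdict(self)
        d["_note"] = (
            "noise magnitudes and efficacies are generator assumptions, "
            "not field measurements"
        )
        return json.dumps(d, indent=2, default=default)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Fixed-order sub-streams of the bundle seed."""
    names = ("forcing", "pam", "gas", "chamber", "inc_morning", "inc_afternoon",
             "profiles")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def gen_forcing(truth: SyntheticTruth, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sensor-log table: time_h, par, uva, uvb, air_temp_c, wind_ms."""
    f = truth.forcing
    if not f.sunrise_h < f.sunset_h:
        raise ValidationError("sunrise must precede sunset")
    if f.timestep_min <= 0:
        raise ValidationError("timestep must be positive")
    rng = rng or _streams(truth.seed)["forcing"]

    t = np.arange(0.0, 24.0 + 1e-9, f.timestep_min / 60.0)
    daylight = (t >= f.sunrise_h) & (t <= f.sunset_h)
    phase = np.where(
        daylight, np.sin(np.pi * (t - f.sunrise_h) / (f.sunset_h - f.sunrise_h)), 0.0
    )
    noise = np.exp(rng.normal(0.0, f.noise_sigma, size=(3, t.size)))
    par = f.peak_par * phase * np.where(daylight, noise[0], 1.0)
    uva = f.peak_uva * phase * np.where(daylight, noise[1], 1.0)
    uvb = f.peak_uvb * phase * np.where(daylight, noise[2], 1.0)

    mid = 0.5 * (f.temp_min_c + f.temp_max_c)
    amp = 0.5 * (f.temp_max_c - f.temp_min_c)
    temp = mid + amp * np.cos(2 * np.pi * (t - f.temp_peak_h) / 24.0)

    r0, r1 = f.wind_ramp_h
    frac = np.clip((t - r0) / (r1 - r0), 0.0, 1.0)
    wind = f.wind_low_ms + (f.wind_high_ms - f.wind_low_ms) * frac

    return pd.DataFrame(
        {"time_h": t, "par": par, "uva": uva, "uvb": uvb,
         "air_temp_c": temp, "wind_ms": wind}
    )


def gen_profiles(
    truth: SyntheticTruth, n: int = 1, e0: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> list[IrradianceProfile]:
    """Depth-irradiance profiles from the true K_d (optionally noisy)."""
    rng = rng or _streams(truth.seed)["profiles"]
    z = np.asarray(truth.profile_depths_cm, dtype=float)
    out = []
    for i in range(n):
        e = attenuate(e0, truth.kd_true, z)
        if truth.profile_noise_sigma > 0:
            e = e * np.exp(rng.normal(0.0, truth.profile_noise_sigma, z.size))
        out.append(IrradianceProfile(z, e, site_id=f"synthetic-{i}", timestamp=""))
    return out


def gen_pam_trace(
    truth: SyntheticTruth, forcing: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """PAM record table sampled every ``sample_every_h`` over the light period.

    Yield II is ``baseline * (1 - coupling * E / peak_par)`` plus noise, so
    its minimum coincides with the irradiance maximum by construction.
    Fv/Fm carries a Gaussian-bump midday depression centred near solar noon
    and an afternoon level set by ``recovery_fraction``.
    """
    p, f = truth.photo, truth.forcing
    if not (0.0 <= p.midday_depression < 1.0):
        raise DomainError("midday depression must lie in [0, 1)")
    rng = rng or _streams(truth.seed)["pam"]

    t = np.arange(f.sunrise_h, f.sunset_h + 1e-9, p.sample_every_h)
    e = np.interp(t, forcing["time_h"], forcing["par"])

    y = p.yield_baseline * (1.0 - p.coupling * e / f.peak_par)
    y = y + rng.normal(0.0, p.noise_sigma, t.size)
    y = np.clip(y, 1e-6, 1.0)

    bump = np.exp(-(((t - p.depression_center_h) / p.depression_width_h) ** 2))
    fvfm = p.fvfm_baseline * (1.0 - p.midday_depression * bump)
    # blend the late-afternoon tail toward the configured recovery level
    tail = np.clip((t - p.depression_center_h) / (f.sunset_h - p.depression_center_h), 0, 1)
    fvfm = fvfm * (1.0 - tail) + tail * p.fvfm_baseline * p.recovery_fraction * (
        1.0 - p.midday_depression * bump
    )
    fvfm = np.clip(fvfm + rng.normal(0.0, p.noise_sigma, t.size), 1e-6, 1.0)

    fm_prime = np.full(t.size, p.fm_scale)
    return pd.DataFrame(
        {
            "time_h": t,
            "f": (1.0 - y) * fm_prime,
            "fm_prime": fm_prime,
            "fo": (1.0 - fvfm) * p.fm_scale,
            "fm": np.full(t.size, p.fm_scale),
            "e_par": e,
            "compartment": "sediment_mat",
        }
    )


def gen_gas_field(
    truth: SyntheticTruth, rng: np.random.Generator | None = None,
    chamber_rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, ChamberSeries], pd.DataFrame]:
    """Vial table, chamber series per gas, and the true dissolved field.

    Returns ``(vials, chambers, truth_table)`` where ``vials`` has one row
    per gas x sample hour x replicate with forward-partitioned headspace
    mole fractions, and ``truth_table`` records the noiseless dissolved
    concentrations the vials encode.
    """
    g = truth.gas
    for gas, mean in g.mean_mol_l.items():
        if mean < 0:
            raise DomainError(f"negative mean concentration for {gas}")
    streams = None
    if rng is None or chamber_rng is None:
        streams = _streams(truth.seed)
    rng = rng or streams["gas"]
    chamber_rng = chamber_rng or streams["chamber"]

    vial_rows, truth_rows = [], []
    for gas, mean in g.mean_mol_l.items():
        peak = g.phase_peak_h[gas]
        for hour in g.sample_hours:
            c_true = mean * (1.0 + g.rel_amplitude * np.cos(2 * np.pi * (hour - peak) / 24.0))
            truth_rows.append({"gas": gas, "time_h": hour, "dissolved_mol_l": c_true})
            for rep in range(g.n_replicates):
                c = c_true * (1.0 + rng.normal(0.0, g.noise_rel)) if g.noise_rel > 0 else c_true
                c = max(c, 0.0)
                ppm = partition_to_headspace(
                    c, gas, g.water_temp_c, g.salinity,
                    g.vial_volume_ml, g.headspace_volume_ml, g.pressure_atm,
                )
                vial_rows.append(
                    {
                        "gas": gas,
                        "headspace_ppm": ppm,
                        "vial_volume_ml": g.vial_volume_ml,
                        "headspace_volume_ml": g.headspace_volume_ml,
                        "temp_c": g.water_temp_c,
                        "salinity": g.salinity,
                        "pressure_atm": g.pressure_atm,
                        "timestamp": f"{int(hour):02d}:{int(round((hour % 1) * 60)):02d}",
                        "replicate": f"r{rep + 1}",
                    }
                )

    chambers: dict[str, ChamberSeries] = {}
    times = np.asarray(g.chamber_times_min, dtype=float)
    for gas, slope in g.chamber_slopes_ppm_min.items():
        start = g.atmosphere_ppm[gas]
        ppm = start + slope * times
        sd = g.chamber_noise_ppm[gas]
        if sd > 0:
            ppm = ppm + chamber_rng.normal(0.0, sd, times.size)
        chambers[gas] = ChamberSeries(
            gas=gas,
            times_min=times,
            mole_fraction_ppm=ppm,
            chamber_volume_l=g.chamber_volume_l,
            chamber_area_m2=g.chamber_area_m2,
            temp_c=g.chamber_temp_c,
            pressure_atm=g.pressure_atm,
        )

    return pd.DataFrame(vial_rows), chambers, pd.DataFrame(truth_rows)


def gen_incubation(
    truth: SyntheticTruth, session: str, rng: np.random.Generator | None = None
) -> IncubationExperiment:
    """Endpoint nitrite incubation for one session from the reveal matrix."""
    inc = truth.incubation
    if session not in ("morning", "afternoon"):
        raise ValidationError("session must be 'morning' or 'afternoon'")
    if rng is None:
        rng = _streams(truth.seed)[f"inc_{session}"]
    st: IncubationSessionTruth = getattr(inc, session)
    matrix = inc.reveal_matrix()
    comps = np.array([st.r_aob, st.r_aoa, st.r_other])

    treatments: dict[str, list[tuple[float, float]]] = {}
    for label, coeff in matrix.items():
        rate = st.control_rate + float(np.dot(coeff, comps))
        reps = []
        for _ in range(inc.n_replicates):
            final = inc.initial_um + rate * inc.duration_h
            if inc.noise_sigma_um > 0:
                final += rng.normal(0.0, inc.noise_sigma_um)
            reps.append((inc.initial_um, final))
        treatments[label] = reps
    return IncubationExperiment(
        session=session,
        analyte="nitrite",
        duration_h=inc.duration_h,
        treatments=treatments,
        metadata={"inhibitor_doses": dict(inc.doses)},
    )


@dataclass(frozen=True)
class SyntheticBundle:
    """Full set of stage inputs plus the truth that generated them."""

    truth: SyntheticTruth
    forcing: pd.DataFrame
    profiles: list[IrradianceProfile]
    pam: pd.DataFrame
    vials: pd.DataFrame
    chambers: dict[str, ChamberSeries]
    gas_truth: pd.DataFrame
    incubations: dict[str, IncubationExperiment]

    def write(self, outdir) -> None:
        """Write all tables (CSV) plus truth.json into ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.forcing.to_csv(out / "forcing.csv", index=False)
        prof_rows = []
        for p in self.profiles:
            for z, e in zip(p.depth_cm, p.e_par):
                prof_rows.append(
                    {"depth_cm": z, "e_par": e, "site_id": p.site_id, "timestamp": p.timestamp}
                )
        pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)
        self.pam.to_csv(out / "pam.csv", index=False)
        self.vials.to_csv(out / "gas_vials.csv", index=False)
        ch_rows = []
        for gas, s in self.chambers.items():
            for t, y in zip(s.times_min, s.mole_fraction_ppm):
                ch_rows.append(
                    {
                        "gas": gas,
                        "time_min": t,
                        "ppm": y,
                        "chamber_volume_l": s.chamber_volume_l,
                        "chamber_area_m2": s.chamber_area_m2,
                        "temp_c": s.temp_c,
                        "pressure_atm": s.pressure_atm,
                    }
                )
        pd.DataFrame(ch_rows).to_csv(out / "chamber.csv", index=False)
        inc_rows = []
        for session, exp in self.incubations.items():
            for label, reps in exp.treatments.items():
                for k, (i0, f1) in enumerate(reps):
                    inc_rows.append(
                        {
                            "session": session,
                            "analyte": exp.analyte,
                            "treatment": label,
                            "replicate": f"r{k + 1}",
                            "initial_um": i0,
                            "final_um": f1,
                            "duration_h": exp.duration_h,
                        }
                    )
        pd.DataFrame(inc_rows).to_csv(out / "incubations.csv", index=False)
        (out / "truth.json").write_text(self.truth.to_json())


def make_bundle(
    seed: int = 0, truth: SyntheticTruth | None = None, n_profiles: int = 3
) -> SyntheticBundle:
    """Generate the complete input bundle for one diel cycle."""
    if truth is None:
        truth = SyntheticTruth(seed=seed)
    elif truth.seed != seed:
        truth = dataclasses.replace(truth, seed=seed)
    streams = _streams(truth.seed)
    forcing = gen_forcing(truth, streams["forcing"])
    profiles = gen_profiles(truth, n=n_profiles, rng=streams["profiles"])
    pam = gen_pam_trace(truth, forcing, streams["pam"])
    vials, chambers, gas_truth = gen_gas_field(truth, streams["gas"], streams["chamber"])
    incubations = {
        s: gen_incubation(truth, s, streams[f"inc_{s}"]) for s in ("morning", "afternoon")
    }
    return SyntheticBundle(
        truth=truth,
        forcing=forcing,
        profiles=profiles,
        pam=pam,
        vials=vials,
        chambers=chambers,
        gas_truth=gas_truth,
        incubations=incubations,
    )
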