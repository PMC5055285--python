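"""Seeded synthetic environmental forcing and multi-logger robomussel records.

The generator emulates the statistical structure of multi-year intertidal
deployments: diurnal and seasonal air-temperature cycles with autocorrelated
weather noise, a clear-sky solar curve modulated by autocorrelated cloud
transmission, harmonic tides, positive autocorrelated wind and wave-height
processes, and a "true" mussel body temperature that follows the steady-state
heat budget during emersion and sea-surface temperature during submersion.
Loggers at the same site differ by a fixed microsite offset, random
wave-splash events (instantaneous reset to SST while emersed, more likely as
the water line approaches the logger), and i.i.d. instrument noise.

All randomness flows from one seed. Draw order for the environment is:
air-temperature noise, cloud transmission, wind, wave height, SST noise.
Each logger uses its own substream keyed by (seed, logger index), drawing
first its microsite offset, then splash uniforms, then instrument noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import solar as solar_mod
from .exposure import wave_runup
from .models import HeatBudgetParams, steady_state_temperature
from .series import BodyTemperatureSeries, validate_environment


@dataclass(frozen=True)
class SiteConfig:
    """Identity and geometry of a study site."""

    site_id: str
    latitude: float  # degrees, [-90, 90]
    longitude: float  # degrees east
    utc_offset: float  # hours, local standard time = UTC + utc_offset
    logger_elevation: float = 1.5  # m above MLLW (mid-intertidal)
    shore_slope: float = 0.2  # rise/run
    n_loggers: int = 3

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude must be in [-90, 90]")
        if self.logger_elevation <= 0:
            raise ValueError("logger_elevation must be positive")
        if self.n_loggers < 1:
            raise ValueError("n_loggers must be >= 1")
        if self.shore_slope <= 0:
            raise ValueError("shore_slope must be positive")


#: Default tidal constituents (amplitude m, period h, phase rad): a mixed
#: semidiurnal regime — M2, K1 and S2 at amplitudes typical of the NE Pacific.
DEFAULT_CONSTITUENTS = (
    (0.8, 12.4206, 0.0),
    (0.4, 23.9345, 1.0),
    (0.25, 12.0, 2.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator.

    Defaults describe one heat-stress summer at a temperate Pacific shore:
    warm clear spells with mussel body temperatures reaching the
    high-sub-optimal band, SST well below daytime air temperature, and
    instrument noise at the ~2 deg C fidelity of biomimetic loggers.
    """

    seed: int = 0
    start: str = "2007-06-01"
    end: str = "2007-09-01"
    cadence_minutes: int = 10
    # Air temperature.
    mean_air_temp: float = 14.0  # deg C annual mean
    seasonal_amplitude: float = 6.0  # deg C, peak in late July
    diurnal_amplitude: float = 5.0  # deg C, peak mid-afternoon
    air_noise_sd: float = 1.5  # deg C
    air_noise_persistence_hours: float = 6.0
    # Solar / cloud.
    cloud_persistence: float = 6.0  # hours, AR(1) time constant
    # Tide.
    tidal_constituents: tuple = DEFAULT_CONSTITUENTS
    mean_tide_level: float = 0.9  # m above MLLW
    # Wind and waves.
    mean_wind: float = 3.0  # m/s
    wind_sd: float = 1.5
    wind_persistence_hours: float = 6.0
    mean_wave_height: float = 1.0  # m
    wave_sd: float = 0.4
    wave_persistence_hours: float = 12.0
    # SST.
    mean_sst: float = 12.0  # deg C
    sst_seasonal_amplitude: float = 2.0
    sst_noise_sd: float = 0.3
    sst_persistence_hours: float = 48.0
    # Logger truth.
    truth_model: str = "heat_budget"  # or "air_proxy"
    heat_budget_params: HeatBudgetParams = field(default_factory=HeatBudgetParams)
    microsite_offset_sd: float = 2.0  # deg C between-logger offset scale
    splash_rate: float = 0.05  # probability per emersed hour at the water line
    splash_proximity_scale: float = 0.5  # m, e-folding of splash odds with height gap
    instrument_noise_sd: float = 2.0  # deg C logger fidelity
    runup_coefficient: float = 1.0

    def __post_init__(self):
        if 60 % self.cadence_minutes != 0:
            raise ValueError("cadence_minutes must divide 60")
        if not 0.0 <= self.splash_rate <= 1.0:
            raise ValueError("splash_rate must be in [0, 1]")
        for name in ("seasonal_amplitude", "diurnal_amplitude", "instrument_noise_sd",
                     "microsite_offset_sd", "air_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ValueError("end must be after start")


def _ar1(rng: np.random.Generator, n: int, dt_hours: float, persistence_hours: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with unit-lag time constant ``persistence_hours``."""
    if sd == 0.0:
        rng.normal(size=n)  # keep the draw order stable regardless of sd
        return np.zeros(n)
    if persistence_hours <= 0:
        return rng.normal(0.0, sd, n)
    phi = float(np.exp(-dt_hours / persistence_hours))
    innov = rng.normal(0.0, sd, n)
    innov[0] /= np.sqrt(1.0 - phi**2)  # start in stationarity
    x = lfilter([1.0], [1.0, -phi], innov)
    return x * np.sqrt(1.0 - phi**2)


def _timestamps(cfg: GeneratorConfig) -> pd.DatetimeIndex:
    return pd.date_range(cfg.start, cfg.end, freq=f"{cfg.cadence_minutes}min", inclusive="left")


def _site_key(site: SiteConfig) -> int:
    """Stable per-site entropy so different sites see different weather."""
    return zlib.crc32(site.site_id.encode())


def generate_environment(site: SiteConfig, cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate a complete environmental forcing record for one site.

    Deterministic for a fixed (site, config): same seed, bit-identical output.
    """
    idx = _timestamps(cfg)
    if len(idx) == 0:
        raise ValueError("empty date range")
    n = len(idx)
    dt_hours = cfg.cadence_minutes / 60.0
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), _site_key(site), 0]))

    doy = idx.dayofyear.to_numpy(dtype=float)
    local_hour = (
        idx.hour.to_numpy(dtype=float) + idx.minute.to_numpy(dtype=float) / 60.0 + site.utc_offset
    )

    seasonal = cfg.seasonal_amplitude * np.cos(2.0 * np.pi * (doy - 202.0) / 365.25)
    diurnal = cfg.diurnal_amplitude * np.cos(2.0 * np.pi * (local_hour - 15.0) / 24.0)
    air = (
        cfg.mean_air_temp
        + seasonal
        + diurnal
        + _ar1(rng, n, dt_hours, cfg.air_noise_persistence_hours, cfg.air_noise_sd)
    )

    clear = solar_mod.clear_sky_irradiance(idx, site.latitude, site.longitude)
    cloud_latent = _ar1(rng, n, dt_hours, cfg.cloud_persistence, 1.0)
    transmission = np.clip(0.85 + 0.35 * cloud_latent, 0.05, 1.0)
    solar = clear * transmission  # exactly 0 whenever elevation <= 0

    wind = np.clip(
        cfg.mean_wind + _ar1(rng, n, dt_hours, cfg.wind_persistence_hours, cfg.wind_sd), 0.0, None
    )
    wave = np.clip(
        cfg.mean_wave_height + _ar1(rng, n, dt_hours, cfg.wave_persistence_hours, cfg.wave_sd),
        0.0,
        None,
    )
    sst = (
        cfg.mean_sst
        + cfg.sst_seasonal_amplitude * np.cos(2.0 * np.pi * (doy - 232.0) / 365.25)
        + _ar1(rng, n, dt_hours, cfg.sst_persistence_hours, cfg.sst_noise_sd)
    )

    hours_since_start = (idx.asi8 - idx.asi8[0]) / 3.6e12
    tide = np.full(n, cfg.mean_tide_level, dtype=float)
    for amplitude, period, phase in cfg.tidal_constituents:
        tide += amplitude * np.cos(2.0 * np.pi * hours_since_start / period + phase)

    df = pd.DataFrame(
        {
            "air_temp": air,
            "solar": solar,
            "wind": wind,
            "sig_wave_height": wave,
            "tide_height": tide,
            "sst": sst,
        },
        index=idx,
    )
    return validate_environment(df)


def generate_truth_loggers(
    env: pd.DataFrame, site: SiteConfig, cfg: GeneratorConfig
) -> list[BodyTemperatureSeries]:
    """Generate one "observed" body-temperature series per logger.

    Truth = steady-state heat budget during emersion (or air temperature if
    ``cfg.truth_model == "air_proxy"``) and SST during submersion, plus a
    per-logger microsite offset while emersed, instantaneous wave-splash
    resets to SST, and i.i.d. instrument noise everywhere. Deterministic per
    (seed, logger index).
    """
    if site.n_loggers < 1:
        raise ValueError("n_loggers must be >= 1")
    validate_environment(env)
    idx = env.index
    n = len(idx)
    dt_hours = (idx.asi8[1] - idx.asi8[0]) / 3.6e12 if n >= 2 else 1.0

    runup = wave_runup(env["sig_wave_height"].to_numpy(), site.shore_slope, cfg.runup_coefficient)
    wet_level = env["tide_height"].to_numpy() + runup
    emersed = wet_level < site.logger_elevation

    if cfg.truth_model == "heat_budget":
        base = steady_state_temperature(
            env["air_temp"].to_numpy(),
            env["solar"].to_numpy(),
            env["wind"].to_numpy(),
            cfg.heat_budget_params,
        )
    elif cfg.truth_model == "air_proxy":
        base = env["air_temp"].to_numpy(dtype=float).copy()
    else:
        raise ValueError(f"unknown truth_model {cfg.truth_model!r}")

    sst = env["sst"].to_numpy()
    gap = np.clip(site.logger_elevation - wet_level, 0.0, None)
    # Per-instant splash probability: splash_rate per hour right at the water
    # line, decaying exponentially with the height gap.
    p_splash = np.where(
        emersed,
        np.clip(cfg.splash_rate * dt_hours * np.exp(-gap / cfg.splash_proximity_scale), 0.0, 1.0),
        0.0,
    )

    loggers: list[BodyTemperatureSeries] = []
    for i in range(site.n_loggers):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), _site_key(site), 1, i]))
        offset = rng.normal(0.0, cfg.microsite_offset_sd) if cfg.microsite_offset_sd > 0 else 0.0
        splash_u = rng.uniform(size=n)
        noise = (
            rng.normal(0.0, cfg.instrument_noise_sd, n)
            if cfg.instrument_noise_sd > 0
            else np.zeros(n)
        )
        body = np.where(emersed, base + offset, sst)
        splashed = emersed & (splash_u < p_splash)
        body = np.where(splashed, sst, body)
        body = body + noise
        loggers.append(
            BodyTemperatureSeries(
                temps=pd.Series(body, index=idx, name="body_temp"),
                site_id=site.site_id,
                microsite_id=f"logger{i + 1}",
                source="observed",
            )
        )
    return loggers
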