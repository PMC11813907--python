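"""Synthetic greenhouse cohort generator.

No public dataset of per-fruit tomato diameter trajectories exists at the
scale this pipeline needs, so this module simulates one: a seasonal
greenhouse temperature log, flowers opening throughout the season, latent
sigmoid mass trajectories on the thermal-time axis, caliper measurement
schedules with noise, and a harvest rule whose thermal threshold drops as
the growing period warms.  The simulator emits exactly the CSV artifacts
the real-data path consumes, so downstream modules cannot tell it apart
from field data.

Generative model (per fruit, cultivar parameters theta):

* mean temperature over the nominal growth period, Tbar, from the
  greenhouse log;
* final-size factor  f(Tbar) = max(0.5, 1 - temp_penalty * (Tbar - T_opt)^2);
* asymptotic mass     M ~ Normal(mass_mean * f(Tbar), sd_early),
  truncated > 0, where sd_early = mass_sd * sqrt(1 - late_frac);
* late-growth factor: a fraction ``late_frac`` of the cultivar's mass
  variance is only realised after the early anchor window (cell expansion
  and ripening outcomes that no early measurement can see).  A mean-one
  lognormal factor exp(w(tau) * (eps - sigma^2/2)), with
  eps ~ Normal(0, sigma), sigma = mass_sd * sqrt(late_frac) / mass_mean
  and w(tau) ramping 0 -> 1 between ``late_onset`` and
  ``harvest_tau_base``, multiplies the trajectory.  High-variability
  cultivars are therefore intrinsically harder to predict early, and
  late-window anchors see more of the final size than early ones;
* trajectory          m(tau) = M * logistic(growth_rate * (tau - mid))
                               * late_factor(tau),
  with a per-fruit midpoint  mid ~ Normal(growth_midpoint, midpoint_sd) —
  timing jitter that further decouples early size from final size;
* harvest threshold   tau_H = harvest_tau_base
                              + harvest_temp_slope * (Tbar - T_opt),
  with a negative slope so warm periods need fewer degree-days;
* diameters by inverse allometry  s = (6 m / (pi * density * a))^(1/3),
  l = a * s, aspect a ~ Normal(aspect_mean, aspect_sd), plus independent
  Normal(0, diameter_noise_sd) per caliper reading;
* measurements every ``measurement_interval`` days from fruit set
  (tau ~ 50 degC d) until harvest; harvest mass m(tau_H) plus weighing
  noise.

An exactly-cubic trajectory family (``growth_shape="cubic"``, a smoothstep
in tau) is provided for end-to-end validation: with all noise switched off
the cubic fitting stage recovers it exactly.

Default cultivar parameters are calibrated to published cultivar-level
statistics for "CF Momotaro York", "Zayda" and "Adventure" (harvest mass
154.3 +/- 51.5, 140.9 +/- 27.4 and 152.0 +/- 39.2 g; densities 1.005,
1.072 and 0.970 g cm^-3; diameters around 6-7 cm).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ConfigError, CoverageError, DomainError
from .thermal_time import TemperatureSeries, ThermalClock

__all__ = [
    "CultivarParams",
    "TempProfile",
    "SimConfig",
    "FruitRecord",
    "CULTIVARS",
    "default_config",
    "simulate_temperature",
    "simulate_fruit",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CultivarParams:
    """Generative parameters for one cultivar."""

    name: str
    mass_mean: float  # g, asymptotic mass at the temperature optimum
    mass_sd: float  # g, fruit-to-fruit spread of asymptotic mass
    density: float  # g cm^-3
    aspect_mean: float  # long/short diameter ratio
    aspect_sd: float
    growth_midpoint: float = 450.0  # degC d, logistic inflection
    growth_rate: float = 0.008  # (degC d)^-1
    midpoint_sd: float = 80.0  # degC d, per-fruit timing jitter
    late_frac: float = 0.5  # fraction of mass variance realised late
    late_onset: float = 500.0  # degC d where the late factor starts ramping
    late_knee: float = 800.0  # degC d boundary between the two late stages
    late_split: float = 0.6  # share of late variance realised after the knee
    harvest_tau_base: float = 1000.0  # degC d to harvest at T_opt
    harvest_temp_slope: float = -30.0  # degC d per degC, negative
    temp_optimum: float = 19.5  # degC
    temp_penalty: float = 0.002  # per degC^2 reduction of final size

    def __post_init__(self) -> None:
        if min(self.mass_mean, self.mass_sd, self.density) <= 0:
            raise DomainError("mass_mean, mass_sd and density must be positive")
        if self.aspect_mean < 1:
            raise DomainError("aspect_mean must be >= 1 (long >= short)")
        if self.harvest_tau_base <= self.growth_midpoint:
            raise DomainError("harvest_tau_base must exceed growth_midpoint")
        if not (0 <= self.late_frac < 1):
            raise DomainError("late_frac must be in [0, 1)")
        if not (0 <= self.late_split <= 1):
            raise DomainError("late_split must be in [0, 1]")
        if not (self.late_onset < self.late_knee < self.harvest_tau_base):
            raise DomainError("need late_onset < late_knee < harvest_tau_base")


#: cultivar presets calibrated to published per-cultivar harvest statistics
CULTIVARS: Dict[str, CultivarParams] = {
    "CF Momotaro York": CultivarParams(
        "CF Momotaro York", mass_mean=154.3, mass_sd=51.5, density=1.005,
        aspect_mean=6.7 / 6.4, aspect_sd=0.03,
    ),
    "Zayda": CultivarParams(
        "Zayda", mass_mean=140.9, mass_sd=27.4, density=1.072,
        aspect_mean=6.4 / 6.2, aspect_sd=0.02,
    ),
    "Adventure": CultivarParams(
        "Adventure", mass_mean=152.0, mass_sd=39.2, density=0.970,
        aspect_mean=6.7 / 6.6, aspect_sd=0.025,
    ),
}


@dataclass(frozen=True)
class TempProfile:
    """Sinusoidal seasonal mean path plus daily Gaussian jitter.

    Defaults give roughly 22 degC in mid-summer falling to 17 degC in
    mid-winter — typical set points for heated tomato greenhouses.
    """

    annual_mean: float = 19.5  # degC
    amplitude: float = 2.5  # degC
    peak_doy: int = 196  # day of year of the warm peak (mid July)
    jitter_sd: float = 1.5  # degC, day-to-day

    def path(self, days: np.ndarray) -> np.ndarray:
        doy = (days - days.astype("datetime64[Y]")).astype(int)
        return self.annual_mean + self.amplitude * np.cos(
            2 * np.pi * (doy - self.peak_doy) / 365.25
        )


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated greenhouse experiment."""

    cultivars: Tuple[CultivarParams, ...]
    n_fruits: int = 300  # per cultivar
    season_start: _dt.date = _dt.date(2022, 9, 1)
    season_end: _dt.date = _dt.date(2023, 6, 30)
    temp_profile: TempProfile = field(default_factory=TempProfile)
    measurement_interval: float = 3.5  # days; 3.5 = once or twice a week
    diameter_noise_sd: float = 0.05  # cm per caliper reading
    harvest_noise_sd: float = 5.0  # g on the harvest weighing
    calib_noise_sd: float = 3.0  # g on destructive calibration masses
    n_calibration: int = 150  # per cultivar
    fruit_set_tau: float = 50.0  # degC d: first measurable fruit
    growth_shape: str = "logistic"  # or "cubic" (validation family)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fruits < 1:
            raise ConfigError("n_fruits must be >= 1")
        if self.measurement_interval < 1:
            raise ConfigError("measurement_interval must be >= 1 day")
        if self.season_end <= self.season_start:
            raise ConfigError("empty season")
        if self.growth_shape not in ("logistic", "cubic"):
            raise ConfigError(f"unknown growth_shape {self.growth_shape!r}")


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The standard three-cultivar experiment with published-statistics presets."""
    return SimConfig(cultivars=tuple(CULTIVARS.values()), seed=seed, **overrides)


@dataclass(frozen=True)
class FruitRecord:
    """One fruit as the field notebook would record it."""

    fruit_id: str
    cultivar: str
    anthesis: _dt.date
    measurements: Tuple[Tuple[_dt.date, float, float], ...]  # (date, long, short)
    harvest_date: Optional[_dt.date] = None
    harvest_mass_g: Optional[float] = None


def simulate_temperature(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> TemperatureSeries:
    """Daily greenhouse temperature log over the configured season."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    days = np.arange(
        np.datetime64(config.season_start, "D"),
        np.datetime64(config.season_end, "D") + 1,
    )
    if days.size == 0:
        raise ConfigError("empty season")
    path = config.temp_profile.path(days)
    temps = path + rng.normal(0.0, config.temp_profile.jitter_sd, size=days.size)
    return TemperatureSeries(days=days, temps=temps)


def _late_sigmas(params: CultivarParams) -> Tuple[float, float]:
    """Relative SDs of the two late-growth stages (before/after the knee)."""
    var_rel = params.late_frac * (params.mass_sd / params.mass_mean) ** 2
    return (
        math.sqrt(var_rel * (1.0 - params.late_split)),
        math.sqrt(var_rel * params.late_split),
    )


def _latent_mass(
    tau: np.ndarray,
    M: float,
    params: CultivarParams,
    mid: float,
    eps: Tuple[float, float],
    shape: str,
) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if shape != "logistic":
        u = np.clip(tau / params.harvest_tau_base, 0.0, 1.0)
        return M * (3 * u**2 - 2 * u**3)  # smoothstep: exactly cubic in tau
    base = M / (1.0 + np.exp(-params.growth_rate * (tau - mid)))
    s1, s2 = _late_sigmas(params)
    if s1 == 0 and s2 == 0:
        return base
    # two mean-one lognormal late-growth stages: onset->knee, knee->harvest
    w1 = np.clip(
        (tau - params.late_onset) / (params.late_knee - params.late_onset), 0.0, 1.0
    )
    w2 = np.clip(
        (tau - params.late_knee) / (params.harvest_tau_base - params.late_knee),
        0.0,
        1.0,
    )
    log_f = w1 * (eps[0] - 0.5 * s1**2) + w2 * (eps[1] - 0.5 * s2**2)
    return base * np.exp(log_f)


def simulate_fruit(
    params: CultivarParams,
    clock: ThermalClock,
    rng: np.random.Generator,
    config: SimConfig,
    fruit_id: str = "fruit-0000",
) -> FruitRecord:
    """Simulate one fruit on its thermal clock.

    Draw order (fixed for reproducibility): asymptotic mass M (rejection
    sampling until positive), aspect ratio, growth midpoint, late-growth
    deviation, one pair of diameter-noise draws per reading,
    harvest-weighing noise.
    """
    series = clock.series
    anth_idx = (np.datetime64(clock.anthesis, "D") - series.days[0]).astype(int)
    cum = series._cum  # degree-days at day boundaries
    rel = cum[anth_idx:] - cum[anth_idx]  # thermal time at boundaries >= anthesis

    def tau_at(day_offset: int) -> float:
        return float(rel[day_offset])

    def day_reaching(target: float) -> int:
        idx = int(np.searchsorted(rel, target, side="left"))
        if idx >= rel.size:
            raise CoverageError(
                f"fruit {fruit_id}: {target:.0f} degC d not reachable before season end"
            )
        return idx

    # nominal growth-period mean temperature (anthesis -> harvest_tau_base)
    d_base = day_reaching(params.harvest_tau_base)
    if d_base == 0:
        raise CoverageError(f"fruit {fruit_id}: zero-length growth period")
    tbar = tau_at(d_base) / d_base

    f = max(0.5, 1.0 - params.temp_penalty * (tbar - params.temp_optimum) ** 2)
    sd_early = params.mass_sd * math.sqrt(1.0 - params.late_frac)
    M = rng.normal(params.mass_mean * f, sd_early)
    while M <= 0:
        M = rng.normal(params.mass_mean * f, sd_early)
    aspect = max(1.0, rng.normal(params.aspect_mean, params.aspect_sd))
    if config.growth_shape == "logistic":
        mid = rng.normal(params.growth_midpoint, params.midpoint_sd)
        mid = float(np.clip(mid, 100.0, params.harvest_tau_base - 100.0))
        s1, s2 = _late_sigmas(params)
        eps = (
            float(rng.normal(0.0, s1)) if s1 > 0 else 0.0,
            float(rng.normal(0.0, s2)) if s2 > 0 else 0.0,
        )
    else:
        mid = params.growth_midpoint  # unused by the cubic family
        eps = (0.0, 0.0)

    tau_h = params.harvest_tau_base + params.harvest_temp_slope * (
        tbar - params.temp_optimum
    )
    tau_h = max(tau_h, config.fruit_set_tau + 1.0)
    d_harvest = day_reaching(tau_h)

    # caliper schedule: from fruit set until (strictly before) harvest
    d_set = day_reaching(config.fruit_set_tau)
    offsets: List[int] = []
    i = 0
    while True:
        d = d_set + int(round(i * config.measurement_interval))
        if d >= d_harvest:
            break
        if not offsets or d > offsets[-1]:
            offsets.append(d)
        i += 1

    measurements = []
    start = np.datetime64(clock.anthesis, "D")
    for d in offsets:
        m = float(_latent_mass(tau_at(d), M, params, mid, eps, config.growth_shape))
        volume = max(m, 1e-9) / params.density
        s = (6.0 * volume / (math.pi * aspect)) ** (1.0 / 3.0)
        l = aspect * s
        noise = rng.normal(0.0, config.diameter_noise_sd, size=2) if config.diameter_noise_sd > 0 else np.zeros(2)
        l_obs = max(0.05, l + noise[0])
        s_obs = max(0.05, s + noise[1])
        date = (start + d).astype(_dt.date)
        measurements.append((date, float(l_obs), float(s_obs)))

    h_mass = float(_latent_mass(tau_h, M, params, mid, eps, config.growth_shape))
    if config.harvest_noise_sd > 0:
        h_mass += float(rng.normal(0.0, config.harvest_noise_sd))
    h_mass = max(h_mass, 1.0)
    return FruitRecord(
        fruit_id=fruit_id,
        cultivar=params.name,
        anthesis=clock.anthesis,
        measurements=tuple(measurements),
        harvest_date=(start + d_harvest).astype(_dt.date),
        harvest_mass_g=h_mass,
    )


def _slug(name: str) -> str:
    return name.lower().replace(" ", "-")


def simulate_cohort(
    config: SimConfig,
) -> Tuple[TemperatureSeries, List[FruitRecord], Dict[str, List[Tuple[float, float]]]]:
    """Simulate the full experiment: temperature log, fruit cohorts per
    cultivar with staggered anthesis dates, and destructive density-
    calibration pairs per cultivar.

    Fully deterministic for a fixed config (one seeded generator, fixed
    draw order: temperature log, then per cultivar its anthesis dates,
    fruits in id order, then its calibration pairs).
    """
    rng = np.random.default_rng(config.seed)
    series = simulate_temperature(config, rng)

    # latest anthesis day leaving enough degree-days for the coolest harvest
    margin = abs(config.cultivars[0].harvest_temp_slope) if config.cultivars else 0.0
    required = max(c.harvest_tau_base for c in config.cultivars) + 4.0 * max(
        abs(c.harvest_temp_slope) for c in config.cultivars
    ) + 100.0
    remaining = series._cum[-1] - series._cum[:-1]
    ok = np.nonzero(remaining >= required)[0]
    if ok.size == 0:
        raise CoverageError("season too short for any fruit to reach harvest")
    latest = int(ok[-1])

    fruits: List[FruitRecord] = []
    calibration: Dict[str, List[Tuple[float, float]]] = {}
    for params in config.cultivars:
        anth_days = np.sort(rng.integers(0, latest + 1, size=config.n_fruits))
        for i, d in enumerate(anth_days):
            anthesis = (series.days[0] + int(d)).astype(_dt.date)
            clock = ThermalClock(anthesis=anthesis, series=series)
            fid = f"{_slug(params.name)}-{i:04d}"
            fruits.append(simulate_fruit(params, clock, rng, config, fruit_id=fid))
        # destructive calibration fruits across growth stages
        v_hi = (params.mass_mean + 2 * params.mass_sd) / params.density
        vols = rng.uniform(5.0, v_hi, size=config.n_calibration)
        noise = rng.normal(0.0, config.calib_noise_sd, size=config.n_calibration) if config.calib_noise_sd > 0 else np.zeros(config.n_calibration)
        masses = np.maximum(params.density * vols + noise, 0.1)
        calibration[params.name] = list(zip(vols.tolist(), masses.tolist()))
    return series, fruits, calibration
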