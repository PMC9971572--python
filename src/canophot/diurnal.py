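"""Diurnal disaggregation of daily weather.

Turns one day of station-level weather (daily solar radiation total,
Tmax/Tmin, humidity) into the hourly drivers the canopy model needs:
direct/diffuse PAR, air temperature (used as leaf temperature) and vapour
pressure deficit, on solar time.

Disaggregation choices (all deterministic):

* global radiation distributed over daylight in proportion to the sine of
  solar elevation, normalised so the hourly energies sum exactly to the
  daily total;
* hourly diffuse fraction from the clearness index via the three-segment
  Erbs correlation;
* PAR taken as half the global shortwave energy, converted at
  4.57 umol J-1;
* air temperature a piecewise cosine with minimum at sunrise and maximum at
  ``peak_hour`` (default 14:00 solar time);
* VPD from the Tetens saturation curve against a day-constant actual vapour
  pressure derived from daily humidity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

SOLAR_CONSTANT = 1367.0     # W m-2
PAR_ENERGY_FRACTION = 0.5   # PAR : global shortwave energy
UMOL_PER_J_PAR = 4.57       # umol photons per J of PAR energy


class UnsupportedLatitudeError(ValueError):
    """Polar day/night is outside the model's scope."""


@dataclass(frozen=True)
class DailyWeather:
    """One day of station weather.

    latitude (deg, |lat| <= 66), day_of_year (1-366), radiation_daily
    (MJ m-2 d-1 global shortwave), Tmax/Tmin (C), humidity as either
    ``rh`` (%) or ``ea_kPa`` (actual vapour pressure), Ca (umol mol-1).
    """

    latitude: float
    day_of_year: int
    radiation_daily: float
    Tmax: float
    Tmin: float
    rh: Optional[float] = None
    ea_kPa: Optional[float] = None
    Ca: float = 400.0

    def __post_init__(self) -> None:
        if abs(self.latitude) > 66:
            raise UnsupportedLatitudeError(
                f"latitude {self.latitude} outside supported range |lat| <= 66")
        if not 1 <= self.day_of_year <= 366:
            raise ValueError("day_of_year must be in 1..366")
        if self.radiation_daily < 0:
            raise ValueError("radiation_daily must be >= 0")
        if self.Tmax < self.Tmin:
            raise ValueError("Tmax must be >= Tmin")
        if self.rh is not None and not 0 <= self.rh <= 100:
            raise ValueError("rh must be within [0, 100] %")
        if self.rh is None and self.ea_kPa is None:
            raise ValueError("provide rh or ea_kPa")


@dataclass(frozen=True)
class HourlyEnvironment:
    """One simulation time step (solar time)."""

    hour: float
    PAR_direct: float      # umol photons m-2 s-1 incident
    PAR_diffuse: float
    Ta: float              # C
    VPD: float             # kPa
    solar_elevation: float  # deg
    Ca: float = 400.0


# ---------------------------------------------------------------------------
# solar geometry
# ---------------------------------------------------------------------------

def solar_declination(day_of_year: int) -> float:
    """Solar declination, degrees: 23.45 sin(360 (284 + DOY) / 365)."""
    return 23.45 * math.sin(math.radians(360.0 * (284 + day_of_year) / 365.0))


def solar_position(latitude: float, day_of_year: int,
                   hour: float) -> tuple[float, float, float, float]:
    """(declination, elevation, sunrise, sunset) in degrees / solar hours.

    Sunrise and sunset are symmetric about solar noon (12:00).
    """
    if abs(latitude) > 66:
        raise UnsupportedLatitudeError(
            f"latitude {latitude} outside supported range |lat| <= 66")
    decl = solar_declination(day_of_year)
    phi, delta = math.radians(latitude), math.radians(decl)
    hour_angle = math.radians(15.0 * (hour - 12.0))
    sin_h = (math.sin(phi) * math.sin(delta)
             + math.cos(phi) * math.cos(delta) * math.cos(hour_angle))
    elevation = math.degrees(math.asin(max(-1.0, min(1.0, sin_h))))
    cos_h0 = -math.tan(phi) * math.tan(delta)
    cos_h0 = max(-1.0, min(1.0, cos_h0))
    half_day = math.degrees(math.acos(cos_h0)) / 15.0
    return decl, elevation, 12.0 - half_day, 12.0 + half_day


# ---------------------------------------------------------------------------
# radiation
# ---------------------------------------------------------------------------

def diffuse_fraction(clearness_index: float) -> float:
    """Erbs three-segment diffuse fraction of global radiation."""
    kt = max(clearness_index, 0.0)
    if kt <= 0.22:
        return 1.0 - 0.09 * kt
    if kt <= 0.80:
        return (0.9511 - 0.1604 * kt + 4.388 * kt ** 2
                - 16.638 * kt ** 3 + 12.336 * kt ** 4)
    return 0.165


def hourly_radiation(daily: DailyWeather, dt: float = 1.0):
    """Per-interval (hour, global W m-2, PAR_direct, PAR_diffuse umol m-2 s-1).

    Interval centres span the day at step ``dt`` hours; the sum of interval
    energies equals ``radiation_daily`` exactly (by normalisation).
    """
    n = int(round(24.0 / dt))
    hours = [(i + 0.5) * dt for i in range(n)]
    sins = []
    for h in hours:
        _, elev, _, _ = solar_position(daily.latitude, daily.day_of_year, h)
        sins.append(max(math.sin(math.radians(elev)), 0.0))
    total = sum(sins)
    out = []
    ecc = 1.0 + 0.033 * math.cos(2.0 * math.pi * daily.day_of_year / 365.0)
    for h, s in zip(hours, sins):
        if total == 0.0 or s == 0.0 or daily.radiation_daily == 0.0:
            out.append((h, 0.0, 0.0, 0.0))
            continue
        energy_mj = daily.radiation_daily * s / total           # MJ m-2 per dt
        g_wm2 = energy_mj * 1e6 / (dt * 3600.0)
        i0 = SOLAR_CONSTANT * ecc * s                            # extraterrestrial
        kt = g_wm2 / i0 if i0 > 0 else 0.0
        fd = diffuse_fraction(kt)
        par_total = g_wm2 * PAR_ENERGY_FRACTION * UMOL_PER_J_PAR
        out.append((h, g_wm2, par_total * (1.0 - fd), par_total * fd))
    return out


# ---------------------------------------------------------------------------
# temperature and humidity
# ---------------------------------------------------------------------------

def hourly_temperature(Tmax: float, Tmin: float, hour: float,
                       sunrise: float, peak_hour: float = 14.0) -> float:
    """Piecewise-cosine diurnal temperature.

    Minimum at sunrise, maximum at ``peak_hour``; after the peak the
    temperature relaxes toward the next sunrise minimum.  Always bounded in
    [Tmin, Tmax].
    """
    if Tmax < Tmin:
        raise ValueError("Tmax must be >= Tmin")
    mid = 0.5 * (Tmax + Tmin)
    amp = 0.5 * (Tmax - Tmin)
    if sunrise <= hour <= peak_hour:
        frac = (hour - sunrise) / (peak_hour - sunrise)
        return mid - amp * math.cos(math.pi * frac)
    # falling branch: from the peak to the next day's sunrise
    if hour > peak_hour:
        span = (sunrise + 24.0) - peak_hour
        frac = (hour - peak_hour) / span
    else:  # pre-dawn: continue the previous day's decay
        span = (sunrise + 24.0) - peak_hour
        frac = (hour + 24.0 - peak_hour) / span
    return mid + amp * math.cos(math.pi * frac)


def saturation_vapour_pressure(T: float) -> float:
    """Tetens saturation vapour pressure, kPa."""
    return 0.6108 * math.exp(17.27 * T / (T + 237.3))


def hourly_vpd(Ta: float, rh: Optional[float] = None,
               ea_kPa: Optional[float] = None) -> float:
    """Vapour pressure deficit e_s(Ta) - e_a, clamped at >= 0 (kPa).

    Humidity enters either as relative humidity ``rh`` (%) evaluated at
    ``Ta``, or as an actual vapour pressure ``ea_kPa`` passed through.
    """
    if not math.isfinite(Ta):
        raise ValueError("Ta must be finite")
    es = saturation_vapour_pressure(Ta)
    if rh is not None:
        if not 0 <= rh <= 100:
            raise ValueError("rh must be within [0, 100] %")
        ea = rh / 100.0 * es
    elif ea_kPa is not None:
        ea = ea_kPa
    else:
        raise ValueError("provide rh or ea_kPa")
    vpd = es - ea
    if vpd < 0:
        import warnings
        warnings.warn("supersaturated input: VPD clamped to 0", stacklevel=2)
        return 0.0
    return vpd


def build_day(daily: DailyWeather, dt: float = 1.0) -> list[HourlyEnvironment]:
    """Full hourly environment for one day at time step ``dt`` hours.

    The actual vapour pressure is held constant over the day, derived from
    daily humidity at the mean temperature when given as RH.
    """
    _, _, sunrise, _ = solar_position(daily.latitude, daily.day_of_year, 12.0)
    if daily.ea_kPa is not None:
        ea = daily.ea_kPa
    else:
        t_mean = 0.5 * (daily.Tmax + daily.Tmin)
        ea = daily.rh / 100.0 * saturation_vapour_pressure(t_mean)
    out = []
    for h, _, par_dir, par_dif in hourly_radiation(daily, dt):
        _, elev, _, _ = solar_position(daily.latitude, daily.day_of_year, h)
        ta = hourly_temperature(daily.Tmax, daily.Tmin, h, sunrise)
        vpd = max(saturation_vapour_pressure(ta) - ea, 0.0)
        out.append(HourlyEnvironment(
            hour=h, PAR_direct=par_dir, PAR_diffuse=par_dif, Ta=ta,
            VPD=vpd, solar_elevation=elev, Ca=daily.Ca))
    return out
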