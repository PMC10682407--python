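"""Mean-radiant-temperature simulation from site, time and sky condition.

The chain is: solar geometry -> clear-sky shortwave -> cloud/override
attenuation -> surface & longwave budget -> flux composition on a standing
body.  Formula dialects (all frozen, documented here):

* Solar geometry: Fourier-series declination / equation of time
  (Spencer 1971) with hour-angle astronomy.
* Direct beam: Beer extinction ``I = I0 * E0 * exp(-0.8662 * TL * m * dR(m))``
  with Kasten-Young relative air mass ``m``, Rayleigh optical thickness
  ``dR``, Linke turbidity ``TL`` and station-pressure correction
  ``exp(-z/8434)``.
* Clear-sky diffuse: Liu-Jordan transmittance coupling
  ``taud = 0.2710 - 0.2939 * taub``.
* Cloud attenuation: Kasten-Czeplak ``G = Gmax * (1 - 0.75*(N/8)**3.4)``.
* Atmospheric emissivity: Angstrom-type ``0.82 - 0.25*10**(-0.094*VP)``
  with cloud factor ``1 + 0.22*(N/8)**2``.
* Standing-body projected-area factor
  ``fp = 0.308 * cos(beta*(0.998 - beta**2/50000))`` with ``beta`` the solar
  elevation in degrees.
"""

from __future__ import annotations

import math
import time as _time
import warnings
from dataclasses import dataclass

from .errors import DomainError, UsageError
from .meteo_core import vp_rh_exchange

SOLAR_CONSTANT = 1367.0  # W/m^2
SIGMA = 5.670374419e-8  # Stefan-Boltzmann, W/(m^2 K^4)
SURFACE_EMISSIVITY = 0.97
BODY_EMISSIVITY = 0.97
SCALE_HEIGHT = 8434.0  # m, pressure scale height for station correction

# Longwave angle factors for a standing body (sky/ground/lateral), sum 1.
F_UP = 0.25
F_DOWN = 0.25
F_SIDE = 0.50

_KELVIN = 273.15


@dataclass
class SiteTime:
    """Geographic position plus calendar/clock fields for solar geometry.

    When any of ``day_of_year``/``hour_of_day``/``timezone_offset`` is None,
    the current system local time fills all three ("now" default); tests
    always pass explicit values.
    """

    longitude: float
    latitude: float
    sea_level_height: float = 0.0
    day_of_year: int | None = None
    hour_of_day: float | None = None
    timezone_offset: float | None = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.longitude <= 180.0:
            raise DomainError(f"longitude={self.longitude!r} outside +-180")
        if not -90.0 <= self.latitude <= 90.0:
            raise DomainError(f"latitude={self.latitude!r} outside +-90")
        if None in (self.day_of_year, self.hour_of_day, self.timezone_offset):
            now = _time.localtime()
            if self.day_of_year is None:
                self.day_of_year = now.tm_yday
            if self.hour_of_day is None:
                self.hour_of_day = now.tm_hour + now.tm_min / 60.0 + now.tm_sec / 3600.0
            if self.timezone_offset is None:
                self.timezone_offset = -_time.timezone / 3600.0 + (
                    1.0 if now.tm_isdst else 0.0
                )
        if not 1 <= self.day_of_year <= 366:
            raise DomainError(f"day_of_year={self.day_of_year!r} outside 1-366")
        if not 0.0 <= self.hour_of_day < 24.0:
            raise DomainError(f"hour_of_day={self.hour_of_day!r} outside [0, 24)")


@dataclass
class RadiationConfig:
    """Optional sky/surface knobs with their documented defaults."""

    N: float = 0.0
    G: float | None = None
    DGratio: float | None = None
    Tob: float | None = None
    ltf: float = 3.0
    OmegaF: float = 1.0
    alb: float = 0.3
    albhum: float = 0.3
    RedGChk: bool = False
    foglimit: float = 90.0
    bowen: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.N <= 8.0:
            raise DomainError(f"N={self.N!r} octas outside [0, 8]")
        if not 0.0 <= self.OmegaF <= 1.0:
            raise DomainError(f"OmegaF={self.OmegaF!r} outside [0, 1]")
        for name in ("alb", "albhum"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise DomainError(f"{name}={a!r} outside [0, 1]")
        if self.ltf <= 0.0:
            raise DomainError(f"ltf={self.ltf!r} must be positive")


@dataclass
class RadiationBudget:
    """The Tmrt_calc output bundle (shortwave, longwave, Tmrt, surface)."""

    Tmrt: float
    VP: float
    Imax: float
    Gmax: float
    Dmax: float
    Itat: float
    Gtat: float
    Dtat: float
    A: float
    Eu: float
    Es: float
    Tob: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Tmrt": self.Tmrt,
            "VP": self.VP,
            "Imax": self.Imax,
            "Gmax": self.Gmax,
            "Dmax": self.Dmax,
            "Itat": self.Itat,
            "Gtat": self.Gtat,
            "Dtat": self.Dtat,
            "A": self.A,
            "Eu": self.Eu,
            "Es": self.Es,
            "Tob": self.Tob,
        }


def solar_position(site: SiteTime) -> tuple[float, float, float]:
    """Solar zenith (deg), azimuth (deg, N=0 clockwise) and (r0/r)^2 factor."""
    g = 2.0 * math.pi * (site.day_of_year - 1 + (site.hour_of_day - 12.0) / 24.0) / 365.0
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    eqtime_min = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    earth_sun_factor = (
        1.000110
        + 0.034221 * math.cos(g)
        + 0.001280 * math.sin(g)
        + 0.000719 * math.cos(2 * g)
        + 0.000077 * math.sin(2 * g)
    )
    # true solar time in minutes
    tst = (
        site.hour_of_day * 60.0
        + eqtime_min
        + 4.0 * site.longitude
        - 60.0 * site.timezone_offset
    )
    ha = math.radians(tst / 4.0 - 180.0)
    lat = math.radians(site.latitude)
    cos_zen = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(ha)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    zenith = math.degrees(math.acos(cos_zen))
    # azimuth measured clockwise from north
    sin_zen = math.sin(math.acos(cos_zen))
    if sin_zen < 1e-9:
        azimuth = 0.0
    else:
        cos_az = (math.sin(decl) - math.sin(lat) * cos_zen) / (math.cos(lat) * sin_zen)
        cos_az = min(1.0, max(-1.0, cos_az))
        azimuth = math.degrees(math.acos(cos_az))
        if ha > 0:
            azimuth = 360.0 - azimuth
        azimuth %= 360.0
    return zenith, azimuth, earth_sun_factor


def _relative_air_mass(zenith: float, pressure_ratio: float) -> float:
    """Kasten-Young (1989) relative optical air mass, pressure corrected."""
    return pressure_ratio / (
        math.cos(math.radians(zenith)) + 0.50572 * (96.07995 - zenith) ** -1.6364
    )


def _rayleigh_thickness(m: float) -> float:
    """Rayleigh optical thickness dR(m) (Kasten 1996 polynomial)."""
    m = min(m, 20.0)
    return 1.0 / (
        6.6296 + 1.7513 * m - 0.1202 * m**2 + 0.0065 * m**3 - 0.00013 * m**4
    )


def clear_sky_fluxes(
    zenith: float,
    earth_sun_factor: float,
    sea_level_height: float = 0.0,
    ltf: float = 3.0,
    VP: float = 10.0,
) -> tuple[float, float, float]:
    """Clear-sky maxima (Imax beam, Gmax global, Dmax diffuse), W/m^2."""
    if zenith >= 90.0:
        return 0.0, 0.0, 0.0
    pressure_ratio = math.exp(-max(sea_level_height, 0.0) / SCALE_HEIGHT)
    m = _relative_air_mass(zenith, pressure_ratio)
    taub = math.exp(-0.8662 * ltf * m * _rayleigh_thickness(m))
    i0 = SOLAR_CONSTANT * earth_sun_factor
    imax = i0 * taub
    cos_zen = math.cos(math.radians(zenith))
    taud = max(0.2710 - 0.2939 * taub, 0.0)
    dmax = i0 * cos_zen * taud
    gmax = imax * cos_zen + dmax
    return imax, gmax, dmax


def actual_fluxes(
    clear: tuple[float, float, float],
    N: float = 0.0,
    G_override: float | None = None,
    DGratio: float | None = None,
    RH: float = 50.0,
    foglimit: float = 90.0,
    RedGChk: bool = False,
    zenith: float = 0.0,
    OmegaF: float = 1.0,
) -> tuple[float, float, float]:
    """Current (Itat, Gtat, Dtat) from clear-sky maxima and sky condition.

    Precedence: a measured ``G_override`` wins (optionally reduced by the
    sky-view factor when ``RedGChk``); otherwise the Kasten-Czeplak cloud
    law attenuates ``Gmax``.  At ``RH >= foglimit`` all shortwave is
    treated as diffuse.
    """
    imax, gmax, dmax = clear
    cos_zen = math.cos(math.radians(min(zenith, 90.0)))
    if G_override is not None:
        if G_override < 0.0:
            raise DomainError(f"G={G_override!r} W/m^2 is negative")
        if gmax > 0.0 and G_override > 1.2 * gmax:
            warnings.warn(
                f"G={G_override:.0f} W/m^2 exceeds 1.2*Gmax={1.2 * gmax:.0f}; "
                "value retained (possible sensor spike)",
                stacklevel=2,
            )
        gtat = G_override * (OmegaF if RedGChk else 1.0)
        if zenith >= 90.0 or cos_zen <= 1e-6:
            itat, dtat = 0.0, gtat
        elif DGratio is not None:
            dtat = min(max(DGratio, 0.0), 1.0) * gtat
            itat = (gtat - dtat) / cos_zen
        else:
            dfrac = _diffuse_fraction(gmax, dmax, N)
            dtat = dfrac * gtat
            itat = (gtat - dtat) / cos_zen
    else:
        attn = 1.0 - 0.75 * (N / 8.0) ** 3.4
        gtat = gmax * attn
        itat = imax * (1.0 - N / 8.0)
        dtat = max(gtat - itat * cos_zen, 0.0)
        if cos_zen > 1e-6:
            itat = (gtat - dtat) / cos_zen
        else:
            itat = 0.0
    if imax > 0.0:
        itat = min(itat, imax)
        dtat = max(gtat - itat * cos_zen, 0.0)
    if RH >= foglimit:
        itat, dtat = 0.0, gtat
    return itat, gtat, dtat


def _diffuse_fraction(gmax: float, dmax: float, N: float) -> float:
    """Diffuse share of global under partial cloud (clear-sky base + octas)."""
    base = dmax / gmax if gmax > 0.0 else 1.0
    return min(1.0, base + (N / 8.0) * (1.0 - base))


def atmospheric_emissivity(VP: float, N: float = 0.0) -> float:
    """Angstrom-type clear-sky emissivity with cloud enhancement, capped at 1."""
    ea = 0.82 - 0.25 * 10.0 ** (-0.094 * VP)
    return min(ea * (1.0 + 0.22 * (N / 8.0) ** 2), 1.0)


#: bulk surface exchange coefficient for the Tob balance, W/(m^2 K)
_H_SURFACE = 15.0


def surface_and_longwave(
    Ta: float,
    VP: float,
    N: float = 0.0,
    Gtat: float = 0.0,
    Itat: float = 0.0,
    zenith: float = 90.0,
    alb: float = 0.3,
    bowen: float = 1.0,
    Tob_override: float | None = None,
) -> tuple[float, float, float, float]:
    """Longwave budget (A, Eu, Es) and surface temperature Tob.

    Tob solves a bulk surface energy balance: absorbed shortwave plus net
    longwave against turbulent loss partitioned by the Bowen ratio
    (iterated at most 10 times to 0.1 K).  Eu is surface emission at Tob;
    Es is lateral emission at the 50/50 air/surface mix temperature.
    """
    ta_k = Ta + _KELVIN
    ea = atmospheric_emissivity(VP, N)
    a_flux = ea * SIGMA * ta_k**4
    if Tob_override is not None:
        tob = Tob_override
    else:
        tob = Ta
        h_turb = _H_SURFACE * (1.0 + 1.0 / max(bowen, 1e-6))
        for _ in range(10):
            lw_net = SURFACE_EMISSIVITY * (a_flux - SIGMA * (tob + _KELVIN) ** 4)
            new = Ta + ((1.0 - alb) * Gtat + lw_net) / h_turb
            if abs(new - tob) < 0.1:
                tob = new
                break
            tob = new
    eu = SURFACE_EMISSIVITY * SIGMA * (tob + _KELVIN) ** 4
    t_side = 0.5 * (Ta + tob)
    es_flux = SURFACE_EMISSIVITY * SIGMA * (t_side + _KELVIN) ** 4
    return a_flux, eu, es_flux, tob


def projected_area_factor(zenith: float) -> float:
    """Projected-area factor of a standing person vs solar elevation."""
    beta = max(0.0, 90.0 - zenith)  # solar elevation, deg
    return 0.308 * math.cos(math.radians(beta * (0.998 - beta**2 / 50000.0)))


def tmrt_compose(
    Itat: float,
    Dtat: float,
    Gtat: float,
    A: float,
    Eu: float,
    Es: float,
    zenith: float = 90.0,
    OmegaF: float = 1.0,
    alb: float = 0.3,
    albhum: float = 0.3,
) -> float:
    """Compose the mean radiant flux on a standing body and invert to Tmrt.

    Sky-view factor scales the sky shortwave terms and swaps the blocked
    sky longwave for lateral surround emission, keeping longwave angle
    factors summing to 1 (so an isothermal enclosure returns its own
    temperature exactly).
    """
    for name, val in (("Itat", Itat), ("Dtat", Dtat), ("Gtat", Gtat),
                      ("A", A), ("Eu", Eu), ("Es", Es)):
        if val < 0.0:
            raise DomainError(f"{name}={val!r} W/m^2 is negative")
    ak = 1.0 - albhum
    fp = projected_area_factor(zenith) if zenith < 90.0 else 0.0
    shortwave = ak * (
        fp * Itat * OmegaF + F_UP * Dtat * OmegaF + F_DOWN * alb * Gtat
    )
    longwave = BODY_EMISSIVITY * (
        F_UP * OmegaF * A + F_DOWN * Eu + (F_SIDE + F_UP * (1.0 - OmegaF)) * Es
    )
    sstr = shortwave + longwave
    return (sstr / (BODY_EMISSIVITY * SIGMA)) ** 0.25 - _KELVIN


def tmrt_calc(
    Ta: float,
    v: float = 0.1,
    VP: float | None = None,
    RH: float | None = None,
    site: SiteTime | None = None,
    config: RadiationConfig | None = None,
    **site_kwargs,
) -> RadiationBudget:
    """Simulate Tmrt and the full radiation budget for one time-point.

    ``site`` may be given directly or assembled from keyword fields
    (longitude, latitude, sea_level_height, day_of_year, hour_of_day,
    timezone_offset).
    """
    if site is None:
        try:
            site = SiteTime(**site_kwargs)
        except TypeError as exc:
            raise UsageError(f"invalid or missing site coordinates: {exc}") from exc
    elif site_kwargs:
        raise UsageError("pass either site= or site keyword fields, not both")
    config = config or RadiationConfig()
    if VP is None and RH is None:
        raise UsageError("tmrt_calc needs VP or RH")
    if VP is None:
        VP = vp_rh_exchange(Ta, RH=RH)
    elif RH is None:
        RH = vp_rh_exchange(Ta, VP=VP)
    else:
        implied = vp_rh_exchange(Ta, VP=VP)
        if abs(RH - implied) >= 0.01:
            raise UsageError(
                f"VP={VP} and RH={RH} disagree (implied RH={implied:.3f})"
            )

    zenith, _azimuth, esf = solar_position(site)
    clear = clear_sky_fluxes(zenith, esf, site.sea_level_height, config.ltf, VP)
    itat, gtat, dtat = actual_fluxes(
        clear,
        N=config.N,
        G_override=config.G,
        DGratio=config.DGratio,
        RH=RH,
        foglimit=config.foglimit,
        RedGChk=config.RedGChk,
        zenith=zenith,
        OmegaF=config.OmegaF,
    )
    a_flux, eu, es_flux, tob = surface_and_longwave(
        Ta,
        VP,
        N=config.N,
        Gtat=gtat,
        Itat=itat,
        zenith=zenith,
        alb=config.alb,
        bowen=config.bowen,
        Tob_override=config.Tob,
    )
    tmrt = tmrt_compose(
        itat,
        dtat,
        gtat,
        a_flux,
        eu,
        es_flux,
        zenith=zenith,
        OmegaF=config.OmegaF,
        alb=config.alb,
        albhum=config.albhum,
    )
    return RadiationBudget(
        Tmrt=tmrt,
        VP=VP,
        Imax=clear[0],
        Gmax=clear[1],
        Dmax=clear[2],
        Itat=itat,
        Gtat=gtat,
        Dtat=dtat,
        A=a_flux,
        Eu=eu,
        Es=es_flux,
        Tob=tob,
    )
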