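"""Shared domain types and the two simple auxiliary conversions.

Humidity is exchanged through the Magnus saturation curve over water,
``es = 6.107 * 10**(7.5*Ta/(237.3+Ta))`` hPa, applied for all temperatures
(no ice branch).  Wind is moved between measurement heights with a power-law
profile, default exponent 0.12 (open terrain); the same profile is used for
both the 10 m -> 1.1 m reduction and the 1.1 m -> 10 m conversion needed by
UTCI, so the two directions compose to the identity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import DomainError, UsageError

#: Magnus constants over water (hPa, dimensionless, degC).
MAGNUS_A = 6.107
MAGNUS_B = 7.5
MAGNUS_C = 237.3

#: Default power-law exponent for open terrain.
WIND_PROFILE_EXPONENT = 0.12

#: Reference anthropometric height for all index engines, m.
INDEX_WIND_HEIGHT = 1.1


def saturation_vapor_pressure(Ta: float) -> float:
    """Saturation vapor pressure over water, hPa (Magnus form).

    Parameters
    ----------
    Ta : float
        Air temperature, degC.  Must lie in [-60, 80].
    """
    if not -60.0 <= Ta <= 80.0:
        raise DomainError(
            f"Ta={Ta!r} degC outside the saturation-curve domain [-60, 80]"
        )
    return MAGNUS_A * 10.0 ** (MAGNUS_B * Ta / (MAGNUS_C + Ta))


def vp_rh_exchange(
    Ta: float, VP: float | None = None, RH: float | None = None
) -> float:
    """Exchange vapor pressure (hPa) and relative humidity (%).

    Exactly one of ``VP``/``RH`` must be supplied; the missing one is
    returned.  Supersaturated input (VP > es(Ta)) yields RH capped at 100
    with a warning, since raw station data contain such records.
    """
    if (VP is None) == (RH is None):
        raise UsageError("supply exactly one of VP or RH")
    es = saturation_vapor_pressure(Ta)
    if RH is not None:
        if not 0.0 <= RH <= 100.0:
            raise DomainError(f"RH={RH!r} % outside [0, 100]")
        return RH * es / 100.0
    if VP < 0.0:
        raise DomainError(f"VP={VP!r} hPa is negative")
    rh = 100.0 * VP / es
    if rh > 100.0:
        warnings.warn(
            f"VP={VP:.3f} hPa exceeds saturation es({Ta:.2f})={es:.3f} hPa; "
            "RH capped at 100 %",
            stacklevel=2,
        )
        rh = 100.0
    return rh


def wind_at_height(
    WS: float,
    height: float,
    target_height: float = INDEX_WIND_HEIGHT,
    exponent: float = WIND_PROFILE_EXPONENT,
) -> float:
    """Move a wind speed between heights with a power-law profile.

    ``WS * (target_height/height)**exponent``; multiplicative in height
    ratios, so chained conversions compose exactly.
    """
    if height <= 0.0 or target_height <= 0.0:
        raise DomainError(
            f"heights must be positive (height={height!r}, "
            f"target_height={target_height!r})"
        )
    if WS < 0.0:
        raise DomainError(f"WS={WS!r} m/s is negative")
    return WS * (target_height / height) ** exponent


@dataclass
class MeteoRecord:
    """One time-point of environmental drivers.

    Exactly one of ``VP``/``RH`` may be supplied (the other is filled via
    the saturation curve); supplying both is accepted only when they are
    mutually consistent to 0.01 % RH.
    """

    Ta: float
    v: float
    Tmrt: float
    VP: float | None = None
    RH: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.Ta) or not math.isfinite(self.Tmrt):
            raise DomainError("Ta and Tmrt must be finite")
        if self.v < 0.0:
            raise DomainError(f"v={self.v!r} m/s is negative")
        if self.VP is None and self.RH is None:
            raise UsageError("MeteoRecord needs VP or RH")
        if self.VP is not None and self.RH is not None:
            implied = vp_rh_exchange(self.Ta, VP=self.VP)
            if abs(self.RH - implied) >= 0.01:
                raise UsageError(
                    f"VP={self.VP} and RH={self.RH} disagree through the "
                    f"saturation curve (implied RH={implied:.3f})"
                )
        elif self.VP is None:
            self.VP = vp_rh_exchange(self.Ta, RH=self.RH)
        else:
            self.RH = vp_rh_exchange(self.Ta, VP=self.VP)
        if self.VP < 0.0:
            raise DomainError(f"VP={self.VP!r} hPa is negative")
        if not 0.0 <= self.RH <= 100.0:
            raise DomainError(f"RH={self.RH!r} % outside [0, 100]")


@dataclass
class SubjectProfile:
    """Thermo-physiological and textile parameters of the subject.

    ``icl=None`` means "use the engine's own default": 0.6 clo for PMV and
    0.9 clo for SET*/PET/mPET.  ``auto_clo`` (mPET only) selects clothing
    insulation adapted to the current air temperature.
    """

    icl: float | None = None
    work: float = 80.0
    ht: float = 1.75
    mbody: float = 75.0
    age: float = 35.0
    sex: int = 1
    pos: int = 1
    auto_clo: bool = True

    def __post_init__(self) -> None:
        for name in ("work", "ht", "mbody", "age"):
            if getattr(self, name) <= 0.0:
                raise DomainError(f"{name} must be strictly positive")
        if self.icl is not None and self.icl <= 0.0:
            raise DomainError("icl must be strictly positive when given")
        if self.sex not in (1, 2):
            raise DomainError(f"sex={self.sex!r} not in {{1, 2}}")
        if self.pos not in (1, 2, 3):
            raise DomainError(f"pos={self.pos!r} not in {{1, 2, 3}}")

    def resolved_icl(self, default: float) -> float:
        """Clothing insulation, falling back to the engine default (clo)."""
        return default if self.icl is None else self.icl

    @property
    def dubois_area(self) -> float:
        """DuBois body surface area, m^2."""
        return 0.203 * self.mbody**0.425 * self.ht**0.725

    @property
    def basal_metabolism(self) -> float:
        """Basal metabolic rate, W (Harris-Benedict, converted from kcal/d)."""
        cm = self.ht * 100.0
        if self.sex == 1:
            kcal_day = (
                66.473 + 13.7516 * self.mbody + 5.0033 * cm - 6.755 * self.age
            )
        else:
            kcal_day = (
                655.0955 + 9.5634 * self.mbody + 1.8496 * cm - 4.6756 * self.age
            )
        return kcal_day * 4186.8 / 86400.0

    @property
    def metabolic_rate(self) -> float:
        """Total internal heat production basal + work, W."""
        return self.basal_metabolism + self.work

    @property
    def met_per_area(self) -> float:
        """Metabolic rate per unit DuBois area, W/m^2."""
        return self.metabolic_rate / self.dubois_area

    def replace(self, **kwargs) -> "SubjectProfile":
        """Return a copy with the given fields overridden."""
        state = {
            "icl": self.icl,
            "work": self.work,
            "ht": self.ht,
            "mbody": self.mbody,
            "age": self.age,
            "sex": self.sex,
            "pos": self.pos,
            "auto_clo": self.auto_clo,
        }
        state.update(kwargs)
        return SubjectProfile(**state)
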