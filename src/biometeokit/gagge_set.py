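"""Gagge two-node thermoregulation and the outdoor standard effective
temperature SET*.

The body is a core + skin shell stepped in 1-minute explicit increments
from a neutral start (Tcore 36.8 degC, Tsk 33.7 degC).  Control laws
(constants frozen, classic two-node set):

* skin blood flow  = (6.3 + 120*wsig_core) / (1 + 0.5*csig_skin),
  clamped to [0.5, 90] L/(m^2 h)
* regulatory sweat = 170 * wsig_body * exp(wsig_skin/10.7), <= 500 g/(m^2 h)
* shivering        = 19.4 * csig_skin * csig_core  W/m^2
* skin-mass fraction alpha = 0.0417737 + 0.7451833/(sbf + 0.585417)

SET* is the air temperature of the standard environment (Tmrt = Ta, still
air 0.15 m/s, RH 50 %, clothing matched to the metabolic rate) in which a
subject with the actual final skin temperature and wettedness loses the
same total skin heat; found by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ComputationalError
from .meteo_core import MeteoRecord, SubjectProfile, saturation_vapor_pressure

DEFAULT_ICL = 0.9
STANDARD_AIR_SPEED = 0.15  # m/s, standard-environment still air
STANDARD_RH = 50.0  # %

_SBC = 5.670374419e-8
_LR = 2.2  # Lewis ratio, degC/kPa (with hc in W/m^2K and pressures in kPa: 16.5)
_LEWIS = 16.5  # K/kPa
_TSK_N = 33.7
_TCR_N = 36.8
_TB_N = 36.49
_SKBF_N = 6.3
_ALPHA_N = 0.1
_CSW = 170.0
_CDIL = 120.0
_CSTR = 0.5


@dataclass
class TwoNodeState:
    Tcore: float
    Tsk: float
    skin_blood_flow: float
    sweat_rate: float
    wettedness: float
    alpha: float


def _sat_kpa(t: float) -> float:
    """Saturation vapor pressure, kPa (Antoine form used by the two-node code)."""
    return math.exp(18.6686 - 4030.183 / (t + 235.0)) / 10.0


def _coefficients(v: float, met_w: float, clo: float, tsk: float, tr: float):
    """Convective/radiative/evaporative transfer coefficients.

    Returns (chc, chr, ctc, fcl, h_dry, h_evap) where h_dry is the overall
    skin->air dry conductance W/(m^2 K) through clothing and air film, and
    h_evap the overall evaporative conductance W/(m^2 kPa).
    """
    met_units = met_w / 58.2
    chc_met = 5.66 * max(met_units - 0.85, 0.0) ** 0.39 if met_units > 0.85 else 0.0
    chc = max(3.0, 8.600001 * v**0.53, chc_met)
    chr = 4.0 * 0.72 * _SBC * ((tsk + tr) / 2.0 + 273.15) ** 3
    ctc = chc + chr
    fcl = 1.0 + 0.15 * clo
    rcl = 0.155 * clo
    ra = 1.0 / (fcl * ctc)
    h_dry = 1.0 / (ra + rcl)
    # evaporative: air film + clothing vapor resistance (icl moisture
    # permeability 0.45)
    re_a = 1.0 / (_LEWIS * fcl * chc)
    re_cl = rcl / (_LEWIS * 0.45)
    h_evap = 1.0 / (re_a + re_cl)
    return chc, chr, ctc, fcl, h_dry, h_evap


def two_node_simulate(
    met: MeteoRecord,
    subj: SubjectProfile | None = None,
    minutes: int = 60,
) -> TwoNodeState:
    """Step the two-node equations for `minutes` 1-min increments."""
    subj = subj or SubjectProfile()
    clo = subj.resolved_icl(DEFAULT_ICL)
    ta, tr, v, rh = met.Ta, met.Tmrt, max(met.v, 0.05), met.RH
    adu = subj.dubois_area
    rm = subj.met_per_area  # W/m^2
    pa = rh / 100.0 * _sat_kpa(ta)  # kPa

    tsk, tcr = _TSK_N, _TCR_N
    sbf, alpha = _SKBF_N, _ALPHA_N
    esw_rate = 0.0
    pwet = 0.06

    for _ in range(int(minutes)):
        m = rm
        chc, chr, ctc, fcl, h_dry, h_evap = _coefficients(v, rm, clo, tsk, tr)
        to = (chr * tr + chc * ta) / ctc  # operative temperature

        # thermoregulatory signals
        wsig_sk = max(tsk - _TSK_N, 0.0)
        csig_sk = max(_TSK_N - tsk, 0.0)
        wsig_cr = max(tcr - _TCR_N, 0.0)
        csig_cr = max(_TCR_N - tcr, 0.0)
        tb = alpha * tsk + (1.0 - alpha) * tcr
        wsig_b = max(tb - _TB_N, 0.0)

        sbf = (_SKBF_N + _CDIL * wsig_cr) / (1.0 + _CSTR * csig_sk)
        sbf = min(max(sbf, 0.5), 90.0)
        # skin-mass fraction; capped at 0.35 so the shell never swallows
        # the core under strong vasoconstriction
        alpha = min(0.0417737 + 0.7451833 / (sbf + 0.585417), 0.35)

        regsw = min(_CSW * wsig_b * math.exp(wsig_sk / 10.7), 500.0)
        esw = 0.68 * regsw  # W/m^2 (latent heat of sweat)
        emax = h_evap * (_sat_kpa(tsk) - pa)
        if emax <= 0.0:
            # condensation regime: full wet, all evaporative flux reversed
            pwet = 1.0
            esk = emax
        else:
            prsw = min(esw / emax, 1.0)
            pwet = 0.06 + 0.94 * prsw
            if pwet > 1.0:
                pwet = 1.0
            esk = pwet * emax

        m_shiv = 19.4 * csig_sk * csig_cr
        m = rm + m_shiv

        cres = 0.0014 * m * (34.0 - ta)
        eres = 0.0173 * m * (5.87 - pa)
        dry = h_dry * (tsk - to)

        hf_cr = m - cres - eres - (tcr - tsk) * (5.28 + 1.163 * sbf)
        hf_sk = (tcr - tsk) * (5.28 + 1.163 * sbf) - dry - esk

        tc_cr = 0.97 * (1.0 - alpha) * subj.mbody
        tc_sk = 0.97 * alpha * subj.mbody
        d_cr = hf_cr * adu / (tc_cr * 60.0)
        d_sk = hf_sk * adu / (tc_sk * 60.0)
        if abs(d_cr) > 5.0 or abs(d_sk) > 5.0:
            raise ComputationalError(
                "two-node step instability (|dT| > 5 K/min)",
                details={"d_core": d_cr, "d_skin": d_sk},
            )
        tcr += d_cr
        tsk += d_sk
        esw_rate = regsw

    return TwoNodeState(
        Tcore=tcr,
        Tsk=tsk,
        skin_blood_flow=sbf,
        sweat_rate=esw_rate,
        wettedness=pwet,
        alpha=alpha,
    )


def standard_clothing(met_w: float) -> float:
    """Standard-environment clothing insulation for a metabolic rate, clo."""
    return 1.52 / (met_w / 58.2 + 0.6944) - 0.1835


def _skin_heat_loss(
    tsk: float,
    pwet: float,
    ta: float,
    tr: float,
    v: float,
    rh: float,
    clo: float,
    met_w: float,
) -> float:
    """Total dry + evaporative skin heat loss in a given environment, W/m^2."""
    chc, chr, ctc, fcl, h_dry, h_evap = _coefficients(v, met_w, clo, tsk, tr)
    to = (chr * tr + chc * ta) / ctc
    pa = rh / 100.0 * _sat_kpa(ta)
    return h_dry * (tsk - to) + pwet * h_evap * (_sat_kpa(tsk) - pa)


def set_star(
    met: MeteoRecord,
    subj: SubjectProfile | None = None,
    minutes: int = 60,
) -> float:
    """Standard effective temperature SET*, degC."""
    subj = subj or SubjectProfile()
    clo = subj.resolved_icl(DEFAULT_ICL)
    state = two_node_simulate(met, subj, minutes=minutes)
    met_w = subj.met_per_area
    hsk = _skin_heat_loss(
        state.Tsk, state.wettedness, met.Ta, met.Tmrt, max(met.v, 0.05),
        met.RH, clo, met_w,
    )
    clo_s = standard_clothing(met_w)

    def residual(t: float) -> float:
        return (
            _skin_heat_loss(
                state.Tsk, state.wettedness, t, t,
                STANDARD_AIR_SPEED, STANDARD_RH, clo_s, met_w,
            )
            - hsk
        )

    lo, hi = -50.0, 80.0
    flo, fhi = residual(lo), residual(hi)
    if flo * fhi > 0.0:
        raise ComputationalError(
            "SET* bisection bracket failure",
            details={"bracket": (lo, hi), "residual": (flo, fhi)},
        )
    while hi - lo > 0.01:
        mid = 0.5 * (lo + hi)
        if residual(mid) * flo <= 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
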