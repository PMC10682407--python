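"""Steady-state human energy-balance model (MEMI) and the PET mapping.

The body is a core/skin/clothing column.  Three coupled balances are
solved simultaneously (gains positive, W):

* clothing surface: conduction through the clothing ring equals convective
  plus radiative exchange of the covered surface;
* core->skin transport: internal production net of respiration flows to
  the skin through conduction and vasomotor-controlled blood flow;
* whole body: internal production + radiation + convection + skin
  diffusion + sweat evaporation + respiration sums to zero.

PET is the air temperature of the reference climate (Tmrt = Ta,
v = 0.1 m/s, VP = 12 hPa) at which the whole-body balance closes again
while the actual physiological state (Tcore, Tsk, Tcl, wettedness, sweat
flux) is held fixed; found by bisection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import ComputationalError
from .meteo_core import MeteoRecord, SubjectProfile

DEFAULT_ICL = 0.9

# physical constants of the balance
_P0 = 1013.25  # hPa
_RHO_BLOOD = 1.06  # kg/L
_CB = 3640.0  # J/(kg K), blood
_EM_SK = 0.99
_EM_CL = 0.95
_L_EVAP = 2.42e6  # J/kg
_SIGMA = 5.67e-8
_C_AIR = 1010.0  # J/(kg K)
_R_DIFF_SKIN = 0.79e7  # skin vapor diffusion resistance

# reference climate defining PET
REFERENCE_AIR_SPEED = 0.1  # m/s
REFERENCE_VP = 12.0  # hPa

_FEFF = {1: 0.725, 2: 0.696, 3: 0.67}  # effective radiating area factor


def _vapor_hpa(t: float) -> float:
    """Saturation vapor pressure at skin/expired-air temperature, hPa."""
    return 6.11 * 10.0 ** (7.45 * t / (235.0 + t))


def _basal_metabolism(subj: SubjectProfile) -> float:
    """Basal rate of the balance model, W (body-size/age/sex fit)."""
    shape = subj.ht * 100.0 / subj.mbody ** (1.0 / 3.0)
    if subj.sex == 1:
        return 3.45 * subj.mbody**0.75 * (
            1.0 + 0.004 * (30.0 - subj.age) + 0.010 * (shape - 43.4)
        )
    return 3.19 * subj.mbody**0.75 * (
        1.0 + 0.004 * (30.0 - subj.age) + 0.018 * (shape - 42.1)
    )


@dataclass
class _Geometry:
    adu: float
    facl: float
    fcl: float
    acl: float
    aeff: float
    rcl: float
    htcl: float
    feff: float


def _geometry(subj: SubjectProfile, icl: float) -> _Geometry:
    adu = subj.dubois_area
    feff = _FEFF[subj.pos]
    fcl = 1.0 + 0.31 * icl
    facl = min(
        (-2.36 + 173.51 * icl - 100.76 * icl**2 + 19.28 * icl**3) / 100.0, 1.0
    )
    rcl = icl / 6.45 / facl
    if icl >= 2.0:
        y = 1.0
    elif icl > 0.6:
        y = (subj.ht - 0.2) / subj.ht
    elif icl > 0.3:
        y = 0.5
    else:
        y = 0.1
    r2 = adu * (fcl - 1.0 + facl) / (2.0 * math.pi * subj.ht * y)
    r1 = facl * adu / (2.0 * math.pi * subj.ht * y)
    acl = adu * facl + adu * (fcl - 1.0)
    htcl = (
        2.0 * math.pi * subj.ht * y * (r2 - r1) / (rcl * math.log(r2 / r1) * acl)
    )
    return _Geometry(
        adu=adu, facl=facl, fcl=fcl, acl=acl, aeff=adu * feff, rcl=rcl,
        htcl=htcl, feff=feff,
    )


def _hc(v: float, p: float = _P0) -> float:
    """Convective coefficient, W/(m^2 K)."""
    return (2.67 + 6.5 * max(v, 0.0) ** 0.67) * (p / _P0) ** 0.55


def _respiration(ta: float, vpa: float, met_w: float) -> tuple[float, float]:
    """(sensible, latent) respiratory fluxes, W (losses negative)."""
    tex = 0.47 * ta + 21.0
    rtv = 1.44e-6 * met_w  # ventilation volume flow, m^3/s
    eres = _C_AIR * (ta - tex) * rtv
    erel = 0.623 * _L_EVAP / _P0 * (vpa - _vapor_hpa(tex)) * rtv
    return eres, erel


def _blood_flow(tcore: float, tsk: float) -> float:
    """Skin blood flow with vasomotor control, L/(m^2 h), capped at 90."""
    dilat = max(tcore - 36.6, 0.0)
    constr = max(34.0 - tsk, 0.0)
    return min((6.3 + 75.0 * dilat) / (1.0 + 0.5 * constr), 90.0)


@dataclass
class MEMIState:
    """Converged balance state plus signed flux decomposition (W)."""

    Tcore: float
    Tsk: float
    Tcl: float
    wetsk: float
    h: float
    Ere: float
    csum: float
    rsum: float
    Ed: float
    Esw: float

    @property
    def closure(self) -> float:
        return self.h + self.Ere + self.csum + self.rsum + self.Ed + self.Esw


def _fluxes(
    tcore: float,
    tsk: float,
    tcl: float,
    ta: float,
    tmrt: float,
    vpa: float,
    hc: float,
    geo: _Geometry,
    subj: SubjectProfile,
    h: float,
    met_w: float,
):
    """All body fluxes at a trial state (gains positive, W)."""
    t4 = lambda t: (t + 273.2) ** 4  # noqa: E731
    rbare = geo.aeff * (1.0 - geo.facl) * _EM_SK * _SIGMA * (t4(tmrt) - t4(tsk))
    rclo = geo.feff * geo.acl * _EM_CL * _SIGMA * (t4(tmrt) - t4(tcl))
    rsum = rbare + rclo
    cbare = hc * (ta - tsk) * geo.adu * (1.0 - geo.facl)
    cclo = hc * (ta - tcl) * geo.acl
    csum = cbare + cclo

    # regulatory sweating (mass flow -> latent flux, losses negative)
    tbody = 0.1 * tsk + 0.9 * tcore
    swm = 304.94 * max(tbody - 36.6, 0.0) * geo.adu / 3.6e6  # kg/s
    if subj.sex == 2:
        swm *= 0.7
    vpts = _vapor_hpa(tsk)
    esw_phys = -swm * _L_EVAP
    he = 0.633 * hc / (_P0 * _C_AIR)
    fec = 1.0 / (1.0 + 0.92 * hc * geo.rcl)
    esw_pot = he * (vpa - vpts) * geo.adu * _L_EVAP * fec
    if esw_pot < 0.0:
        wetsk = min(esw_phys / esw_pot, 1.0)
        esw = esw_pot if esw_phys - esw_pot <= 0.0 else esw_phys
    else:  # ambient vapor above skin saturation: no evaporative loss
        wetsk = 1.0 if swm > 0.0 else 0.0
        esw = 0.0
    esw = min(esw, 0.0)

    ed = _L_EVAP / _R_DIFF_SKIN * geo.adu * (1.0 - wetsk) * (vpa - vpts)
    eres, erel = _respiration(ta, vpa, met_w)
    ere = eres + erel
    balance = h + ed + ere + esw + csum + rsum
    return balance, rsum, csum, ed, esw, ere, wetsk


def memi_solve(met: MeteoRecord, subj: SubjectProfile | None = None) -> MEMIState:
    """Solve the steady-state balance for the actual environment."""
    subj = subj or SubjectProfile()
    icl = subj.resolved_icl(DEFAULT_ICL)
    return _memi_solve_env(met.Ta, met.Tmrt, met.v, met.VP, subj, icl)


def _memi_solve_env(
    ta: float,
    tmrt: float,
    v: float,
    vpa: float,
    subj: SubjectProfile,
    icl: float,
) -> MEMIState:
    geo = _geometry(subj, icl)
    met_w = _basal_metabolism(subj) + subj.work
    h = met_w  # mechanical efficiency 0: all production is heat
    hc = _hc(v)
    eres, erel = _respiration(ta, vpa, met_w)
    internal = h + eres + erel  # net heat routed through the skin

    def tcl_of(tsk: float) -> float:
        """Clothing-surface temperature from the covered-area balance."""

        def g(tcl: float) -> float:
            rad = (
                _EM_CL
                * _SIGMA
                * ((tcl + 273.2) ** 4 - (tmrt + 273.2) ** 4)
                * geo.feff
            )
            return geo.htcl * (tsk - tcl) - hc * (tcl - ta) - rad

        lo = min(ta, tmrt, tsk) - 35.0
        hi = max(ta, tmrt, tsk) + 35.0
        return brentq(g, lo, hi, xtol=1e-6)

    def tcore_of(tsk: float) -> float:
        """Core temperature from the core->skin transport balance."""

        def g(tcore: float) -> float:
            cond = 5.28 * geo.adu
            blood = geo.adu * _RHO_BLOOD * _CB * _blood_flow(tcore, tsk) / 3600.0
            return internal - (cond + blood) * (tcore - tsk)

        return brentq(g, tsk - 2.0, tsk + 25.0, xtol=1e-6)

    def residual(tsk: float) -> float:
        tcl = tcl_of(tsk)
        tcore = tcore_of(tsk)
        balance, *_ = _fluxes(
            tcore, tsk, tcl, ta, tmrt, vpa, hc, geo, subj, h, met_w
        )
        return balance

    lo, hi = 0.5, 45.0
    try:
        tsk = brentq(residual, lo, hi, xtol=1e-4)
    except ValueError:
        # strong cold stress can push the vasoconstricted shell below the
        # nominal floor; extend the bracket once before giving up
        try:
            tsk = brentq(residual, -25.0, hi, xtol=1e-4)
        except ValueError as exc:
            raise ComputationalError(
                "no physiological root for the skin temperature",
                details={
                    "bracket": (-25.0, hi),
                    "residual": (residual(-25.0), residual(hi)),
                    "ta": ta, "tmrt": tmrt, "v": v, "vpa": vpa,
                },
            ) from exc
        warnings.warn(
            f"skin temperature {tsk:.1f} degC below the nominal bracket "
            f"floor (Ta={ta}, v={v})",
            stacklevel=2,
        )
    tcl = tcl_of(tsk)
    tcore = tcore_of(tsk)
    balance, rsum, csum, ed, esw, ere, wetsk = _fluxes(
        tcore, tsk, tcl, ta, tmrt, vpa, hc, geo, subj, h, met_w
    )
    return MEMIState(
        Tcore=tcore, Tsk=tsk, Tcl=tcl, wetsk=wetsk, h=h, Ere=ere,
        csum=csum, rsum=rsum, Ed=ed, Esw=esw,
    )


@dataclass
class PETResult:
    PET: float
    Tcore: float
    Tsk: float
    Tcl: float
    wetsk: float
    metabolic_rate: float
    respiratory_flux: float
    convective_flux: float
    radiative_flux: float
    diffuse_flux: float
    sweating_flux: float

    def as_dict(self) -> dict[str, float]:
        return self.__dict__.copy()


def reference_balance(
    tx: float, state: MEMIState, subj: SubjectProfile, icl: float = DEFAULT_ICL
) -> float:
    """Whole-body balance in the reference climate at air temperature tx,
    holding the actual physiological state fixed (W)."""
    geo = _geometry(subj, icl)
    met_w = _basal_metabolism(subj) + subj.work
    hc = _hc(REFERENCE_AIR_SPEED)
    t4 = lambda t: (t + 273.2) ** 4  # noqa: E731
    rbare = geo.aeff * (1.0 - geo.facl) * _EM_SK * _SIGMA * (t4(tx) - t4(state.Tsk))
    rclo = geo.feff * geo.acl * _EM_CL * _SIGMA * (t4(tx) - t4(state.Tcl))
    cbare = hc * (tx - state.Tsk) * geo.adu * (1.0 - geo.facl)
    cclo = hc * (tx - state.Tcl) * geo.acl
    vpts = _vapor_hpa(state.Tsk)
    ed = (
        _L_EVAP / _R_DIFF_SKIN * geo.adu * (1.0 - state.wetsk)
        * (REFERENCE_VP - vpts)
    )
    eres, erel = _respiration(tx, REFERENCE_VP, met_w)
    return state.h + ed + eres + erel + state.Esw + cbare + cclo + rbare + rclo


def pet_calc(met: MeteoRecord, subj: SubjectProfile | None = None) -> PETResult:
    """PET and the 11-field output bundle for one record."""
    subj = subj or SubjectProfile()
    icl = subj.resolved_icl(DEFAULT_ICL)
    state = _memi_solve_env(met.Ta, met.Tmrt, met.v, met.VP, subj, icl)

    def g(tx: float) -> float:
        return reference_balance(tx, state, subj, icl)

    lo, hi = -50.0, 80.0
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0.0:
        raise ComputationalError(
            "PET equivalence root not bracketed",
            details={"bracket": (lo, hi), "balance": (glo, ghi)},
        )
    pet = brentq(g, lo, hi, xtol=0.01)
    return PETResult(
        PET=pet,
        Tcore=state.Tcore,
        Tsk=state.Tsk,
        Tcl=state.Tcl,
        wetsk=state.wetsk,
        metabolic_rate=state.h,
        respiratory_flux=state.Ere,
        convective_flux=state.csum,
        radiative_flux=state.rsum,
        diffuse_flux=state.Ed,
        sweating_flux=state.Esw,
    )
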