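"""Fanger predicted mean vote with equivalent temperature and clothing loss.

The comfort-equation core (`pmv_equation`) takes the classic per-area
inputs (metabolic rate W/m^2, clothing clo, air/radiant temperature, wind,
vapor pressure) and returns PMV plus the converged clothing-surface state.
`pmv_calc` wraps it with the package's subject model: the metabolic rate is
the Harris-Benedict basal rate plus the activity load, divided by the
DuBois area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ComputationalError
from .meteo_core import MeteoRecord, SubjectProfile, saturation_vapor_pressure

#: default clothing insulation for PMV, clo
DEFAULT_ICL = 0.6

_TCL_MAX_ITER = 150
_TCL_TOL = 1e-3  # K


@dataclass
class PMVResult:
    PMV: float
    Teq: float
    hclo: float


@dataclass
class _Balance:
    pmv: float
    load: float
    tcl: float
    hclo: float


def pmv_equation(
    ta: float,
    tr: float,
    v: float,
    pa: float,
    met: float,
    clo: float,
    wme: float = 0.0,
) -> _Balance:
    """Fanger heat-balance: PMV, thermal load and clothing-surface state.

    Parameters are in degC, m/s, Pa (vapor pressure), W/m^2 (met, wme)
    and clo.  Clothing-surface temperature is solved by damped fixed-point
    iteration with the max(natural, forced) convection rule.
    """
    icl = 0.155 * clo  # m^2 K / W
    m = met
    mw = m - wme
    fcl = 1.0 + 1.29 * icl if icl <= 0.078 else 1.05 + 0.645 * icl
    hcf = 12.1 * math.sqrt(max(v, 0.0))
    taa = ta + 273.0
    tra = tr + 273.0

    tcla = taa + (35.5 - ta) / (3.5 * icl + 0.1)  # initial guess
    p1 = icl * fcl
    p2 = p1 * 3.96
    p3 = p1 * 100.0
    p4 = p1 * taa
    p5 = 308.7 - 0.028 * mw + p2 * (tra / 100.0) ** 4
    xn = tcla / 100.0
    xf = tcla / 50.0
    hc = hcf
    n = 0
    eps = 0.00015
    while abs(xn - xf) > eps:
        xf = (xf + xn) / 2.0
        hcn = 2.38 * abs(100.0 * xf - taa) ** 0.25
        hc = max(hcf, hcn)
        xn = (p5 + p4 * hc - p2 * xf**4) / (100.0 + p3 * hc)
        n += 1
        if n > _TCL_MAX_ITER:
            raise ComputationalError(
                "clothing-surface iteration did not converge",
                details={"last_tcl": 100.0 * xn - 273.0, "iterations": n},
            )
    tcl = 100.0 * xn - 273.0

    # heat-loss components, W/m^2
    hl1 = 3.05e-3 * (5733.0 - 6.99 * mw - pa)  # skin diffusion
    hl2 = 0.42 * (mw - 58.15) if mw > 58.15 else 0.0  # sweating comfort term
    hl3 = 1.7e-5 * m * (5867.0 - pa)  # latent respiration
    hl4 = 0.0014 * m * (34.0 - ta)  # dry respiration
    hl5 = 3.96 * fcl * (xn**4 - (tra / 100.0) ** 4)  # radiation
    hl6 = fcl * hc * (tcl - ta)  # convection

    load = mw - hl1 - hl2 - hl3 - hl4 - hl5 - hl6
    ts = 0.303 * math.exp(-0.036 * m) + 0.028
    tsk = 35.7 - 0.028 * mw  # comfort skin temperature
    hclo = (tsk - tcl) / icl if icl > 0.0 else hl5 + hl6
    return _Balance(pmv=ts * load, load=load, tcl=tcl, hclo=hclo)


def _load_uniform(t: float, v: float, rh: float, met: float, clo: float) -> float:
    """Thermal load in a uniform environment (ta = tr = t) at constant RH."""
    pa = rh / 100.0 * saturation_vapor_pressure(t) * 100.0  # Pa
    return pmv_equation(t, t, v, pa, met, clo).load


def equivalent_temperature(
    v: float,
    rh: float,
    met: float,
    clo: float,
    lo: float = -40.0,
    hi: float = 60.0,
    tol: float = 0.01,
) -> float:
    """Uniform temperature zeroing Fanger's load, by bisection."""
    flo = _load_uniform(lo, v, rh, met, clo)
    fhi = _load_uniform(hi, v, rh, met, clo)
    if flo * fhi > 0.0:
        raise ComputationalError(
            "equivalent-temperature root not bracketed",
            details={"bracket": (lo, hi), "load": (flo, fhi)},
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _load_uniform(mid, v, rh, met, clo) * flo <= 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def pmv_calc(met: MeteoRecord, subj: SubjectProfile | None = None) -> PMVResult:
    """Predicted mean vote triple {PMV, Teq, hclo} for one record."""
    subj = subj or SubjectProfile()
    clo = subj.resolved_icl(DEFAULT_ICL)
    m = subj.met_per_area
    pa = met.VP * 100.0  # hPa -> Pa
    bal = pmv_equation(met.Ta, met.Tmrt, met.v, pa, m, clo)
    teq = equivalent_temperature(met.v, met.RH, m, clo)
    return PMVResult(PMV=bal.pmv, Teq=teq, hclo=bal.hclo)
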