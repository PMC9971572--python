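"""Multilayer canopy model: the numerical reference for the two-leaf scheme.

Resolves the canopy into many thin layers and, within each layer, the
sunlit and shaded leaf classes, using exactly the same leaf biochemistry,
radiation profiles and nitrogen distribution as :mod:`canophot.canopy` —
the two-leaf per-fraction quantities are the closed-form depth integrals of
the per-leaf profiles evaluated here.  Disagreement between the two is
therefore purely the aggregation (big-leaf) error, which is what this
module exists to quantify.

Only the fixed-Ci/Ca diffusion mode is supported.
"""
from __future__ import annotations

import math

from .canopy import (
    CanopyState,
    _canopy_reflectances,
    extinction_coefficients,
    sln_top_from_ave,
)
from .diurnal import DailyWeather, HourlyEnvironment, build_day
from .fvcb import (
    DEFAULT_KINETICS,
    KineticConstants,
    arrhenius_response,
    j_light_response,
    solve_coupled_assimilation,
)


def _leaf_area_absorption(ell: float, ib: float, id_: float,
                          kb: float, kd: float, sigma: float):
    """(sunlit extra beam, shared diffuse+scattered) absorbed per unit leaf
    area at cumulative LAI depth ``ell``."""
    rho_cb, rho_cd, sq, _ = _canopy_reflectances(sigma, kb)
    kb_p, kd_p = kb * sq, kd * sq
    q_diffuse = id_ * (1.0 - rho_cd) * kd_p * math.exp(-kd_p * ell)
    q_scatter = ib * ((1.0 - rho_cb) * kb_p * math.exp(-kb_p * ell)
                      - (1.0 - sigma) * kb * math.exp(-kb * ell))
    q_beam_sunlit = ib * (1.0 - sigma) * kb
    return q_beam_sunlit, max(q_diffuse + q_scatter, 0.0)


def hourly_assimilation_multilayer(env: HourlyEnvironment, state: CanopyState,
                                   kin: KineticConstants = DEFAULT_KINETICS,
                                   n_layers: int = 100) -> float:
    """Canopy net assimilation for one hour, umol CO2 m-2 ground s-1."""
    if state.ci_ratio is None:
        raise ValueError("multilayer reference supports the fixed-Ci mode only")
    kb, kd = extinction_coefficients(state.leaf_inclination,
                                     env.solar_elevation, state.kd)
    if kb is None:
        return 0.0
    ta = env.Ta
    kin_eff = kin.at(ta)
    sln_top = sln_top_from_ave(state.sln_ave, state.kn)
    d_ell = state.lai / n_layers
    gm_leaf = arrhenius_response(state.gm25, kin.Ea_gm, ta)
    total = 0.0
    for i in range(n_layers):
        ell = (i + 0.5) * d_ell
        sln = sln_top * math.exp(-state.kn * ell / state.lai)
        eff_n = max(sln - state.sln_b, 0.0)
        vcmax25 = state.chi_v * eff_n
        jmax25 = state.chi_j * eff_n
        rd25 = state.rd_frac * vcmax25
        rd = arrhenius_response(rd25, kin.Ea_Rd, ta) if rd25 > 0 else 0.0
        f_sun = math.exp(-kb * ell)
        q_beam, q_shared = _leaf_area_absorption(
            ell, env.PAR_direct, env.PAR_diffuse, kb, kd, state.sigma)
        layer = 0.0
        for f_class, i_leaf in ((f_sun, q_shared + q_beam),
                                (1.0 - f_sun, q_shared)):
            if f_class <= 0.0:
                continue
            if vcmax25 <= 0.0:
                layer += f_class * (-rd)
                continue
            vcmax = arrhenius_response(vcmax25, kin.Ea_Vcmax, ta)
            jmax = arrhenius_response(jmax25, kin.Ea_Jmax, ta,
                                      deltaS=kin.deltaS_Jmax, Hd=kin.Hd_Jmax)
            j = j_light_response(i_leaf, jmax, state.theta, eff=state.psii_eff)
            sol = solve_coupled_assimilation(
                env.Ca, Vcmax=vcmax, J=j, Rd=rd, TPU=None, gm=gm_leaf,
                kin=kin_eff, ci_ratio=state.ci_ratio)
            layer += f_class * sol.A
        total += layer * d_ell
    return total


def daily_canopy_assimilation_multilayer(
        state: CanopyState, weather: DailyWeather,
        kin: KineticConstants = DEFAULT_KINETICS,
        n_layers: int = 100, dt: float = 1.0) -> float:
    """A_can,day from the multilayer reference, mol CO2 m-2 ground d-1."""
    total_umol = 0.0
    for env in build_day(weather, dt):
        if env.solar_elevation <= 0:
            continue
        total_umol += hourly_assimilation_multilayer(
            env, state, kin, n_layers) * dt * 3600.0
    return total_umol / 1e6
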