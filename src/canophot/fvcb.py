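"""Farquhar–von Caemmerer–Berry (FvCB) C3 leaf photosynthesis.

Forward biochemical model of net CO2 assimilation with the three classical
limitations (Rubisco carboxylation, RuBP regeneration, triose-phosphate
utilisation), Arrhenius-type temperature scaling of the capacities and
kinetic constants, a non-rectangular-hyperbola (NRH) light response of
electron transport, and a closed-form solver that couples assimilation to
stomatal/mesophyll CO2 diffusion.

This module is the shared engine: the curve-fitting routines in
:mod:`canophot.estimation` invert it, and the canopy model in
:mod:`canophot.canopy` drives it per sunlit/shaded fraction.

Units follow gas-exchange convention throughout: rates in umol m-2 s-1,
CO2 mole fractions in umol mol-1, O2 in mmol mol-1, conductances in
mol m-2 s-1, temperatures in degrees Celsius.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

R_GAS = 8.314  # universal gas constant, J mol-1 K-1
T_REF_K = 298.15  # 25 C reference, K

#: limiting-state tie-break order: rubisco < rubp < tpu
_STATE_ORDER = {"rubisco": 0, "rubp": 1, "tpu": 2}


class SolverError(RuntimeError):
    """Coupled diffusion/assimilation solver found no admissible root."""


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if v is None or not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeafPhotoParams:
    """FvCB capacity set at the 25 C reference plus shape constants.

    Vcmax25 : maximum Rubisco carboxylation rate, umol CO2 m-2 s-1
    Jmax25  : maximum electron transport rate, umol e- m-2 s-1
    TPU25   : triose phosphate utilisation rate, umol m-2 s-1
    Rd25    : mitochondrial (day) respiration, umol CO2 m-2 s-1
    gm25    : mesophyll conductance to CO2, mol m-2 s-1
    theta   : NRH curvature of the light response, dimensionless in (0, 1]
    alphabeta : product of leaf absorptance and the fraction of absorbed
        quanta reaching PSII (the slope of A vs PhiPSII*PPFD/4 under
        non-photorespiratory conditions), dimensionless in (0, 1]
    """

    Vcmax25: float
    Jmax25: float
    TPU25: float
    Rd25: float
    gm25: float
    theta: float = 0.7
    alphabeta: float = 0.425

    def __post_init__(self) -> None:
        for name in ("Vcmax25", "Jmax25", "TPU25", "gm25"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Rd25 < 0:
            raise ValueError("Rd25 must be >= 0")
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if not 0 < self.alphabeta <= 1:
            raise ValueError("alphabeta must be in (0, 1]")

    def at(self, T: float, kin: "KineticConstants") -> "LeafRates":
        """Temperature-adjusted rates at leaf temperature ``T`` (C)."""
        return LeafRates(
            Vcmax=arrhenius_response(self.Vcmax25, kin.Ea_Vcmax, T),
            Jmax=arrhenius_response(
                self.Jmax25, kin.Ea_Jmax, T,
                deltaS=kin.deltaS_Jmax, Hd=kin.Hd_Jmax),
            TPU=arrhenius_response(self.TPU25, kin.Ea_TPU, T),
            Rd=arrhenius_response(self.Rd25, kin.Ea_Rd, T) if self.Rd25 > 0 else 0.0,
            gm=arrhenius_response(self.gm25, kin.Ea_gm, T),
            theta=self.theta,
            alphabeta=self.alphabeta,
        )


@dataclass(frozen=True)
class LeafRates:
    """FvCB rates at a specific leaf temperature (same units as at 25 C)."""

    Vcmax: float
    Jmax: float
    TPU: Optional[float]
    Rd: float
    gm: float
    theta: float = 0.7
    alphabeta: float = 0.425


@dataclass(frozen=True)
class EffectiveKinetics:
    """Rubisco kinetics and the CO2 compensation point at one temperature.

    Kc (umol mol-1), Ko (mmol mol-1), O (mmol mol-1), gamma_star (umol mol-1).
    """

    Kc: float
    Ko: float
    O: float
    gamma_star: float

    def __post_init__(self) -> None:
        if min(self.Kc, self.Ko, self.O, self.gamma_star) <= 0:
            raise ValueError("kinetic constants must be positive")

    @property
    def Km(self) -> float:
        """Effective Michaelis constant Kc*(1 + O/Ko), umol mol-1."""
        return self.Kc * (1.0 + self.O / self.Ko)


@dataclass(frozen=True)
class KineticConstants:
    """25 C kinetic constants plus activation energies (J mol-1).

    Defaults are the standard tobacco-derived values used across the C3
    modelling literature; every entry can be overridden, and the set can be
    serialised with :func:`canophot.io.save_config`.
    """

    Kc25: float = 404.9         # umol mol-1
    Ko25: float = 278.4         # mmol mol-1
    GammaStar25: float = 42.75  # umol mol-1
    O: float = 210.0            # mmol mol-1
    Ea_Vcmax: float = 65330.0
    Ea_Jmax: float = 43540.0
    Ea_TPU: float = 53100.0
    Ea_Rd: float = 46390.0
    Ea_Kc: float = 79430.0
    Ea_Ko: float = 36380.0
    Ea_GammaStar: float = 37830.0
    Ea_gm: float = 49600.0
    deltaS_Jmax: Optional[float] = None  # J mol-1 K-1, peaked response if set
    Hd_Jmax: Optional[float] = None      # J mol-1

    def at(self, T: float) -> EffectiveKinetics:
        return EffectiveKinetics(
            Kc=arrhenius_response(self.Kc25, self.Ea_Kc, T),
            Ko=arrhenius_response(self.Ko25, self.Ea_Ko, T),
            O=self.O,
            gamma_star=arrhenius_response(self.GammaStar25, self.Ea_GammaStar, T),
        )


DEFAULT_KINETICS = KineticConstants()

#: Kinetics used by the estimation chain: the CO2 compensation point is held
#: at the protocol constant 40.0 umol mol-1 and Kc/Ko keep their reference
#: values (Km = 710.3 umol mol-1), i.e. no temperature adjustment is applied
#: at the measurement leaf temperature.  Parameters fitted against this set
#: are therefore reference-normalised capacities.
MEASUREMENT_KINETICS = EffectiveKinetics(Kc=404.9, Ko=278.4, O=210.0, gamma_star=40.0)


@dataclass(frozen=True)
class LeafFluxState:
    """Self-consistent leaf CO2 fluxes and internal mole fractions."""

    A: float                 # net assimilation, umol m-2 s-1
    Ci: float                # intercellular CO2, umol mol-1
    Cc: float                # chloroplast CO2, umol mol-1
    limiting_state: str      # 'rubisco' | 'rubp' | 'tpu'


# ---------------------------------------------------------------------------
# elementary responses
# ---------------------------------------------------------------------------

def arrhenius_response(p25: float, Ea: float, T: float,
                       deltaS: Optional[float] = None,
                       Hd: Optional[float] = None) -> float:
    """Scale a rate from 25 C to leaf temperature ``T``.

    p25 * exp[Ea (Tk - 298.15) / (298.15 R Tk)], optionally multiplied by the
    peaked deactivation term (entropy ``deltaS`` J mol-1 K-1, deactivation
    energy ``Hd`` J mol-1).  Exactly the identity at T = 25.
    """
    _require_finite(p25=p25, Ea=Ea, T=T)
    if p25 <= 0:
        raise ValueError("p25 must be > 0")
    if not -10.0 <= T <= 60.0:
        raise ValueError(f"T={T} C outside supported range [-10, 60]")
    Tk = T + 273.15
    value = p25 * math.exp(Ea * (Tk - T_REF_K) / (T_REF_K * R_GAS * Tk))
    if deltaS is not None and Hd is not None:
        num = 1.0 + math.exp((T_REF_K * deltaS - Hd) / (T_REF_K * R_GAS))
        den = 1.0 + math.exp((Tk * deltaS - Hd) / (Tk * R_GAS))
        value *= num / den
    return value


def normalize_to_25(p_at_T: float, Ea: float, T: float) -> float:
    """Invert :func:`arrhenius_response`: refer a rate measured at ``T`` back
    to the 25 C reference (simple-Arrhenius branch only)."""
    return p_at_T / arrhenius_response(1.0, Ea, T)


def measured_leaf_to_reference(Vcmax: float, Jmax: float, TPU: float,
                               gm: float, Rd: Optional[float] = None,
                               *, T_meas: float = 35.0,
                               rd_frac: float = 0.015,
                               kin: Optional["KineticConstants"] = None,
                               theta: float = 0.7,
                               alphabeta: float = 0.425) -> "LeafPhotoParams":
    """Refer leaf capacities measured at leaf temperature ``T_meas`` back to
    the 25 C reference via the inverse Arrhenius step.

    This is the explicit bridge between the measurement side (capacities
    fitted at the instrument leaf temperature) and the canopy model (which
    expects 25 C inputs and re-applies the temperature responses hourly).
    ``Rd`` defaults to ``rd_frac`` of the converted Vcmax25.
    """
    k = kin if kin is not None else DEFAULT_KINETICS
    vc25 = normalize_to_25(Vcmax, k.Ea_Vcmax, T_meas)
    rd25 = (normalize_to_25(Rd, k.Ea_Rd, T_meas) if Rd and Rd > 0
            else rd_frac * vc25)
    return LeafPhotoParams(
        Vcmax25=vc25,
        Jmax25=normalize_to_25(Jmax, k.Ea_Jmax, T_meas),
        TPU25=normalize_to_25(TPU, k.Ea_TPU, T_meas),
        Rd25=rd25,
        gm25=normalize_to_25(gm, k.Ea_gm, T_meas),
        theta=theta, alphabeta=alphabeta)


def j_light_response(I_abs: float, Jmax: float, theta: float,
                     eff: float = 1.0) -> float:
    """Electron transport from the non-rectangular hyperbola.

    Smaller root of theta J^2 - (I2 + Jmax) J + I2 Jmax = 0 with
    I2 = eff * I_abs (useful electrons reaching PSII per incident/absorbed
    photon, depending on the convention carried by ``eff``).
    """
    if theta <= 0 or theta > 1:
        raise ValueError("theta must be in (0, 1]")
    if I_abs < 0:
        raise ValueError("I_abs must be >= 0")
    _require_finite(I_abs=I_abs, Jmax=Jmax)
    I2 = eff * I_abs
    if I2 == 0.0:
        return 0.0
    b = I2 + Jmax
    disc = b * b - 4.0 * theta * I2 * Jmax
    return (b - math.sqrt(max(disc, 0.0))) / (2.0 * theta)


def gross_rates(Cc: float, Vcmax: float, J: float, TPU: Optional[float],
                kin: EffectiveKinetics) -> tuple[float, float, float]:
    """Gross carboxylation rates (Wc, Wj, Wp) at chloroplast CO2 ``Cc``.

    Wc = Vcmax (Cc - G*) / (Cc + Km)
    Wj = J (Cc - G*) / (4 Cc + 8 G*)
    Wp = 3 TPU (independent of Cc; +inf when TPU is None)
    """
    if Cc <= 0:
        raise ValueError("Cc must be > 0")
    g = kin.gamma_star
    Wc = Vcmax * (Cc - g) / (Cc + kin.Km)
    Wj = J * (Cc - g) / (4.0 * Cc + 8.0 * g)
    Wp = math.inf if TPU is None else 3.0 * TPU
    return Wc, Wj, Wp


def net_assimilation_at_cc(Cc: float, *, Vcmax: float, J: float,
                           TPU: Optional[float], Rd: float,
                           kin: EffectiveKinetics) -> tuple[float, str]:
    """Net assimilation min(Wc, Wj, Wp) - Rd with the limiting-state label.

    Ties resolved in the order rubisco < rubp < tpu.
    """
    Wc, Wj, Wp = gross_rates(Cc, Vcmax, J, TPU, kin)
    rates = (("rubisco", Wc), ("rubp", Wj), ("tpu", Wp))
    state, W = min(rates, key=lambda t: (t[1], _STATE_ORDER[t[0]]))
    return W - Rd, state


# ---------------------------------------------------------------------------
# coupled diffusion solver
# ---------------------------------------------------------------------------

def _state_solutions(X: float, r: float, *, Vcmax: float, J: float,
                     TPU: Optional[float], Rd: float,
                     kin: EffectiveKinetics) -> list[tuple[float, str]]:
    """Solve A for each limiting state along the supply line Cc = X - r A.

    For the hyperbolic states W = a (Cc - G*) / (Cc + b) the steady state
    A = W(X - r A) - Rd is the smaller root of
        r A^2 - [X + b + r (a - Rd)] A + a (X - G*) - Rd (X + b) = 0.
    """
    g = kin.gamma_star
    out: list[tuple[float, str]] = []
    for state, a, b in (("rubisco", Vcmax, kin.Km), ("rubp", J / 4.0, 2.0 * g)):
        B = X + b + r * (a - Rd)
        C = a * (X - g) - Rd * (X + b)
        if r <= 1e-12:
            out.append((C / B, state))
            continue
        disc = B * B - 4.0 * r * C
        if disc < 0:
            raise SolverError(
                f"no real root for state {state}: X={X}, r={r}, a={a}, b={b}")
        A = (B - math.sqrt(disc)) / (2.0 * r)
        if X - r * A <= 0:
            raise SolverError(
                f"state {state} drives Cc <= 0: X={X}, r={r}, A={A}")
        out.append((A, state))
    if TPU is not None:
        out.append((3.0 * TPU - Rd, "tpu"))
    return out


def solve_coupled_assimilation(
    Ca: float,
    *,
    Vcmax: float,
    J: float,
    Rd: float,
    kin: EffectiveKinetics,
    TPU: Optional[float] = None,
    gm: float = math.inf,
    ci_ratio: Optional[float] = None,
    gs: Optional[float] = None,
    ball_berry: Optional[tuple[float, float]] = None,
    rh: float = 0.7,
) -> LeafFluxState:
    """Self-consistent (A, Ci, Cc) for one leaf.

    Exactly one diffusion option selects how Ci relates to Ca:

    ``ci_ratio``   fixed Ci/Ca ratio (the default canopy coupling);
    ``gs``         stomatal conductance to water vapour, Ci = Ca - 1.6 A / gs;
    ``ball_berry`` (slope, intercept): gs = slope * A * rh / Ca + intercept,
                   solved by damped fixed-point iteration.

    Mesophyll drawdown Cc = Ci - A/gm (``gm`` may be ``math.inf``).  Each
    limiting state is solved in closed form along the CO2 supply line and the
    minimum-rate rule is applied afterwards.
    """
    if Ca <= 0:
        raise ValueError("Ca must be > 0")
    if gm is not None and gm <= 0:
        raise ValueError("gm must be > 0 (or math.inf)")
    chosen = [o is not None for o in (ci_ratio, gs, ball_berry)]
    if sum(chosen) != 1:
        raise ValueError("choose exactly one of ci_ratio, gs, ball_berry")

    r_m = 0.0 if math.isinf(gm) else 1.0 / gm

    def _solve(X: float, r: float) -> tuple[float, str]:
        sols = _state_solutions(X, r, Vcmax=Vcmax, J=J, TPU=TPU, Rd=Rd, kin=kin)
        return min(sols, key=lambda t: (t[0], _STATE_ORDER[t[1]]))

    if ci_ratio is not None:
        Ci = ci_ratio * Ca
        A, state = _solve(Ci, r_m)
        Cc = Ci - r_m * A
    elif gs is not None:
        if gs <= 0:
            raise ValueError("gs must be > 0")
        r = 1.6 / gs + r_m
        A, state = _solve(Ca, r)
        Ci = Ca - 1.6 * A / gs
        Cc = Ci - r_m * A
    else:
        slope, g0 = ball_berry
        if g0 <= 0:
            raise ValueError("Ball-Berry intercept must be > 0")
        A, state = _solve(0.7 * Ca, r_m)  # warm start from a fixed ratio
        for _ in range(200):
            gs_eff = max(slope * max(A, 0.0) * rh / Ca + g0, g0)
            r = 1.6 / gs_eff + r_m
            A_new, state = _solve(Ca, r)
            if abs(A_new - A) < 1e-11:
                A = A_new
                break
            A = 0.5 * A + 0.5 * A_new
        else:
            raise SolverError("Ball-Berry coupling did not converge")
        gs_eff = max(slope * max(A, 0.0) * rh / Ca + g0, g0)
        Ci = Ca - 1.6 * A / gs_eff
        Cc = Ci - r_m * A

    if Cc <= 0:
        raise SolverError(f"solution has Cc={Cc:.3f} <= 0 (Ca={Ca})")
    return LeafFluxState(A=A, Ci=Ci, Cc=Cc, limiting_state=state)
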