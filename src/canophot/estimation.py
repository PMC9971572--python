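"""Leaf parameter estimation from combined gas exchange and fluorescence.

Implements the measurement-protocol side of the pipeline:

* PSII operating efficiency from modulated fluorescence and the
  fluorescence-based electron transport rate J = PhiPSII * PPFD * alpha*beta;
* calibration of the alpha*beta product and day respiration Rd from a
  low-O2 (non-photorespiratory) light-response curve, where net assimilation
  is linear in PhiPSII*PPFD/4 with slope alpha*beta and intercept -Rd;
* the variable-J estimate of mesophyll conductance gm and the resulting
  A/Ci -> A/Cc curve transformation;
* nonlinear least-squares fitting of the FvCB capacities (Vcmax, Jmax, TPU)
  on the A/Cc curve;
* the mass-weighted canopy-average specific leaf nitrogen SLN_ave.

The CO2 compensation point is held at the protocol constant
``GAMMA_STAR_PROTOCOL`` = 40.0 umol mol-1 (see
:data:`canophot.fvcb.MEASUREMENT_KINETICS`): fitted capacities are
reference-normalised and feed the canopy model directly as 25 C inputs.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .fvcb import (
    MEASUREMENT_KINETICS,
    EffectiveKinetics,
    j_light_response,
    net_assimilation_at_cc,
)

GAMMA_STAR_PROTOCOL = 40.0  # umol mol-1, fixed by the measurement protocol


class DataQualityError(ValueError):
    """Input data violate a physical or protocol constraint."""


class CalibrationError(ValueError):
    """Calibration curve is insufficient for an OLS fit."""


class FitError(RuntimeError):
    """FvCB curve fit failed to converge."""


@dataclass(frozen=True)
class GasExchangeRecord:
    """One combined gas-exchange/fluorescence observation.

    A (umol CO2 m-2 s-1), Ca/Ci (umol mol-1), gs (mol H2O m-2 s-1),
    PPFD (umol photons m-2 s-1), Tleaf (C), Fs/Fm_prime (relative
    fluorescence), O2_percent (%).
    """

    A: float
    Ca: float
    Ci: float
    gs: float
    PPFD: float
    Tleaf: float
    Fs: float
    Fm_prime: float
    O2_percent: float = 21.0

    def __post_init__(self) -> None:
        if self.PPFD < 0:
            raise ValueError("PPFD must be >= 0")
        if self.Fs < 0 or self.Fm_prime < self.Fs:
            raise DataQualityError("fluorescence requires Fm_prime >= Fs >= 0")
        if self.A > 0 and self.Ci > self.Ca:
            raise DataQualityError("Ci > Ca while A > 0")


@dataclass(frozen=True)
class CalibrationResult:
    """alpha*beta and Rd from the low-O2 light-response regression."""

    alphabeta: float
    Rd: float
    slope: float
    intercept: float
    r_squared: float
    se_slope: float
    se_intercept: float
    n: int


@dataclass(frozen=True)
class FittedLeafParams:
    """FvCB capacities fitted on an A/Cc curve (reference-normalised)."""

    Vcmax: float
    Jmax: float
    TPU: Optional[float]
    se: dict = field(default_factory=dict)
    sse: float = float("nan")
    n_points: int = 0
    limiting_states: tuple = ()


@dataclass(frozen=True)
class LeafNitrogenSample:
    """Destructive-harvest sample split into top leaves and the rest.

    N_* in % of dry mass, DM_* in g, LA_* in m2.
    """

    N_o: float
    N_other: float
    DM_o: float
    DM_other: float
    LA_o: float
    LA_other: float

    def __post_init__(self) -> None:
        if min(self.DM_o, self.DM_other, self.LA_o, self.LA_other) < 0:
            raise ValueError("masses and areas must be >= 0")
        if self.LA_o + self.LA_other <= 0:
            raise ValueError("total leaf area must be > 0")


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def phi_psii(Fs: float, Fm_prime: float) -> float:
    """PSII operating efficiency (Fm' - Fs) / Fm'."""
    if Fm_prime <= 0:
        raise ValueError("Fm_prime must be > 0")
    if Fs < 0 or Fs > Fm_prime:
        raise DataQualityError("require 0 <= Fs <= Fm_prime")
    return (Fm_prime - Fs) / Fm_prime


def j_from_fluorescence(phi: float, PPFD: float, alphabeta: float) -> float:
    """Fluorescence-based electron transport J = PhiPSII * PPFD * alpha*beta."""
    if phi < 0 or PPFD < 0 or alphabeta < 0:
        raise ValueError("inputs must be >= 0")
    if alphabeta > 1:
        raise ValueError("alphabeta must be <= 1")
    return phi * PPFD * alphabeta


def calibrate_alphabeta_rd(
    points: Sequence[tuple[float, float, float]],
    rd_clamp: float = 0.2,
) -> CalibrationResult:
    """OLS of A on x = PhiPSII*PPFD/4 over a low-O2 light-response curve.

    Under non-photorespiratory conditions A = alphabeta * x - Rd, so the
    slope is the alpha*beta product and Rd is minus the intercept.  Small
    negative Rd (< ``rd_clamp``) is clamped to zero with a warning.

    ``points`` are (PhiPSII, PPFD, A) triples at >= 2 distinct light levels.
    """
    pts = list(points)
    if len(pts) < 3:
        raise CalibrationError("need at least 3 calibration points")
    ppfds = {round(p[1], 6) for p in pts}
    if len(ppfds) < 2:
        raise CalibrationError("need at least 2 distinct PPFD levels")
    x = np.array([phi * ppfd / 4.0 for phi, ppfd, _ in pts])
    y = np.array([a for _, _, a in pts])
    if np.ptp(x) == 0:
        raise CalibrationError("zero variance in PhiPSII*PPFD/4")
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise DataQualityError(
            f"calibration slope {res.slope:.4f} <= 0: curve is not "
            "assimilation-limited by electron transport")
    rd = -res.intercept
    if rd < 0:
        if rd > -rd_clamp:
            warnings.warn(
                f"calibration intercept implies Rd={rd:.3f} < 0; clamped to 0",
                stacklevel=2)
            rd = 0.0
        else:
            raise DataQualityError(
                f"calibration intercept implies Rd={rd:.3f} << 0")
    return CalibrationResult(
        alphabeta=float(res.slope), Rd=float(rd),
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        se_slope=float(res.stderr), se_intercept=float(res.intercept_stderr),
        n=len(pts))


def calibrate_from_records(records: Sequence[GasExchangeRecord],
                           **kw) -> CalibrationResult:
    """Convenience wrapper: build (PhiPSII, PPFD, A) triples from records."""
    pts = [(phi_psii(r.Fs, r.Fm_prime), r.PPFD, r.A) for r in records]
    return calibrate_alphabeta_rd(pts, **kw)


# ---------------------------------------------------------------------------
# variable-J mesophyll conductance
# ---------------------------------------------------------------------------

def gm_variable_j(A: float, Ci: float, J: float, Rd: float,
                  gamma_star: float = GAMMA_STAR_PROTOCOL) -> float:
    """Variable-J mesophyll conductance.

    gm = A / (Ci - GammaStar * (J + 8 (A + Rd)) / (J - 4 (A + Rd)))

    The denominator's second term is the chloroplast CO2 mole fraction
    implied by the realised electron transport rate J.
    """
    if Ci <= 0:
        raise ValueError("Ci must be > 0")
    if A == 0 and Rd == 0:
        return 0.0
    demand = J - 4.0 * (A + Rd)
    if demand <= 0:
        raise DataQualityError(
            f"electron transport J={J:.2f} inconsistent with assimilation "
            f"(requires J > 4(A+Rd) = {4 * (A + Rd):.2f})")
    cc = gamma_star * (J + 8.0 * (A + Rd)) / demand
    denom = Ci - cc
    if denom <= 0:
        raise DataQualityError(
            f"Ci={Ci:.1f} below the implied chloroplast drawdown Cc={cc:.1f}")
    return A / denom


def cc_from_gm(A: float, Ci: float, gm: float) -> float:
    """Chloroplast CO2 from Fick's law: Cc = Ci - A/gm (gm may be inf)."""
    if gm <= 0:
        raise ValueError("gm must be > 0")
    if math.isinf(gm):
        return Ci
    return Ci - A / gm


def gm_from_curve(
    records: Sequence[GasExchangeRecord],
    alphabeta: float,
    Rd: float,
    gamma_star: float = GAMMA_STAR_PROTOCOL,
    ci_window: tuple[float, float] = (100.0, 400.0),
    summary=np.median,
):
    """Point-wise variable-J gm over an A/Ci curve plus a robust summary.

    Points outside the reliable Ci window (default 100-400 umol mol-1) or
    failing the variable-J preconditions are excluded from the summary but
    reported.  Returns ``(gm_summary, table)`` where ``table`` is a pandas
    DataFrame with per-point J, gm and window membership.
    """
    import pandas as pd

    rows = []
    for i, r in enumerate(records):
        J = j_from_fluorescence(phi_psii(r.Fs, r.Fm_prime), r.PPFD, alphabeta)
        try:
            gm = gm_variable_j(r.A, r.Ci, J, Rd, gamma_star)
            note = ""
        except (DataQualityError, ValueError) as exc:
            gm, note = np.nan, str(exc)
        in_window = (ci_window[0] < r.Ci < ci_window[1]) and np.isfinite(gm) and gm > 0
        rows.append(dict(point=i, A=r.A, Ci=r.Ci, J=J, gm=gm,
                         in_window=in_window, note=note))
    table = pd.DataFrame(rows)
    usable = table.loc[table.in_window, "gm"]
    if usable.empty:
        raise DataQualityError("no usable points in the gm summary window")
    return float(summary(usable.to_numpy())), table


def transform_aci_to_acc(records: Sequence[GasExchangeRecord],
                         gm: float) -> list[tuple[float, float]]:
    """Map an A/Ci curve to (Cc, A) pairs; order and count preserved."""
    out = []
    for i, r in enumerate(records):
        cc = cc_from_gm(r.A, r.Ci, gm)
        if cc <= 0:
            raise DataQualityError(
                f"point {i} (A={r.A:.2f}, Ci={r.Ci:.1f}) maps to Cc={cc:.2f} <= 0")
        out.append((cc, r.A))
    return out


# ---------------------------------------------------------------------------
# FvCB fitting
# ---------------------------------------------------------------------------

_FIT_STARTS = ((60.0, 120.0, 8.0), (100.0, 200.0, 12.0), (200.0, 300.0, 20.0))


def fit_fvcb_params(
    acc_points: Sequence[tuple[float, float]],
    Rd: float,
    kin: EffectiveKinetics = MEASUREMENT_KINETICS,
    *,
    ppfd: float = 1500.0,
    alphabeta: float = 0.425,
    theta: float = 0.7,
    tpu_cc_threshold: float = 300.0,
) -> FittedLeafParams:
    """Least-squares fit of (Vcmax, Jmax, TPU) on an A/Cc curve.

    The model curve is min(Wc, Wj, Wp) - Rd with the electron transport at
    the (saturating) measurement light obtained from the NRH response
    J = NRH(alphabeta * ppfd, Jmax, theta), so Jmax is estimated directly.
    TPU is only a free parameter when the curve reaches
    Cc >= ``tpu_cc_threshold``; without a high-Cc plateau it is reported as
    absent rather than guessed.  Deterministic: bounded trust-region fits
    from three fixed starting points, best SSE wins.
    """
    pts = list(acc_points)
    cc = np.array([p[0] for p in pts], dtype=float)
    a_obs = np.array([p[1] for p in pts], dtype=float)
    fit_tpu = bool(np.any(cc >= tpu_cc_threshold))
    n_free = 3 if fit_tpu else 2
    if len(pts) < max(5, n_free):
        raise ValueError("need at least 5 points spanning the Cc range")

    g = kin.gamma_star
    km = kin.Km

    def model(p: np.ndarray) -> np.ndarray:
        vcmax, jmax = p[0], p[1]
        J = j_light_response(ppfd, jmax, theta, eff=alphabeta)
        wc = vcmax * (cc - g) / (cc + km)
        wj = J * (cc - g) / (4.0 * cc + 8.0 * g)
        w = np.minimum(wc, wj)
        if fit_tpu:
            w = np.minimum(w, 3.0 * p[2])
        return w - Rd

    def residuals(p: np.ndarray) -> np.ndarray:
        return model(p) - a_obs

    lb = [1.0, 1.0, 0.1][:n_free]
    ub = [1000.0, 1500.0, 200.0][:n_free]
    best = None
    for start in _FIT_STARTS:
        x0 = np.array(start[:n_free])
        try:
            # the min-rule model is only piecewise smooth, so a very tight
            # tolerance can exhaust evaluations without "converging"; the
            # returned candidate is still valid and judged on its cost
            sol = optimize.least_squares(residuals, x0, bounds=(lb, ub),
                                         method="trf", max_nfev=2000)
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        if sol.status < 0:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("FvCB fit did not converge from any start")

    p = best.x
    vcmax, jmax = float(p[0]), float(p[1])
    tpu = float(p[2]) if fit_tpu else None

    # per-point limiting states at the optimum
    J = j_light_response(ppfd, jmax, theta, eff=alphabeta)
    states = []
    for c in cc:
        _, state = net_assimilation_at_cc(
            float(c), Vcmax=vcmax, J=J, TPU=tpu, Rd=Rd, kin=kin)
        states.append(state)
    if fit_tpu and "tpu" not in states:
        tpu = None  # plateau never engaged: SSE flat in TPU, value meaningless
        n_free = 2

    sse = float(2.0 * best.cost)
    dof = max(len(pts) - n_free, 1)
    try:
        jac = best.jac[:, :n_free]
        cov = np.linalg.pinv(jac.T @ jac) * sse / dof
        se_vals = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:  # pragma: no cover
        se_vals = np.full(n_free, np.nan)
    se = {"Vcmax": float(se_vals[0]), "Jmax": float(se_vals[1])}
    if tpu is not None and len(se_vals) > 2:
        se["TPU"] = float(se_vals[2])
    return FittedLeafParams(Vcmax=vcmax, Jmax=jmax, TPU=tpu, se=se, sse=sse,
                            n_points=len(pts), limiting_states=tuple(states))


# ---------------------------------------------------------------------------
# canopy-average specific leaf nitrogen
# ---------------------------------------------------------------------------

def sln_ave(sample: LeafNitrogenSample) -> float:
    """Canopy-average specific leaf nitrogen, g N m-2 leaf.

    Mass-weighted leaf N over total leaf area:
        (N_o/100 * DM_o + N_other/100 * DM_other) / (LA_o + LA_other)
    i.e. total leaf nitrogen divided by total leaf area.
    """
    n_total = sample.N_o / 100.0 * sample.DM_o + sample.N_other / 100.0 * sample.DM_other
    return n_total / (sample.LA_o + sample.LA_other)


# ---------------------------------------------------------------------------
# full estimation chain
# ---------------------------------------------------------------------------

def estimate_leaf_parameters(
    aci_records: Sequence[GasExchangeRecord],
    low_o2_records: Sequence[GasExchangeRecord],
    kin: EffectiveKinetics = MEASUREMENT_KINETICS,
    *,
    theta: float = 0.7,
    ci_window: tuple[float, float] = (100.0, 400.0),
) -> dict:
    """Run the complete chain: calibrate -> gm -> A/Cc -> FvCB fit.

    Returns a dict with keys ``calibration`` (:class:`CalibrationResult`),
    ``gm`` (float), ``gm_table`` (DataFrame), ``fit``
    (:class:`FittedLeafParams`) and ``acc_points``.
    """
    cal = calibrate_from_records(low_o2_records)
    gm, gm_table = gm_from_curve(aci_records, cal.alphabeta, cal.Rd,
                                 kin.gamma_star, ci_window=ci_window)
    acc = transform_aci_to_acc(aci_records, gm)
    ppfd = float(np.median([r.PPFD for r in aci_records]))
    fit = fit_fvcb_params(acc, cal.Rd, kin, ppfd=ppfd,
                          alphabeta=cal.alphabeta, theta=theta)
    return {"calibration": cal, "gm": gm, "gm_table": gm_table,
            "fit": fit, "acc_points": acc}
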