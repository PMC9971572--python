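"""Trait-improvement scenario engine.

Two experiment types on top of the daily canopy model:

* **enhancement** — scale one target parameter by a factor (default 1.2,
  i.e. +20%) and report the AM_DAY change;
* **substitution** — set a recipient cultivar's target parameter to a donor
  cultivar's value (internally an enhancement with factor =
  donor/recipient).

Nine targets are supported.  Because total canopy nitrogen
TNC = SLN_ave * LAI, nitrogen-linked targets carry conservation rules:

================  ========================================================
beta              leaf inclination only
gm                leaf gm25 only
Vcmax / Jmax      chi_v / chi_j (capacity per unit nitrogen) only
KN                nitrogen extinction coefficient only
SLN_ave           SLN_ave * f and LAI / f  -> TNC conserved exactly
LAI_can           LAI * f and SLN_ave / f  -> TNC conserved exactly
TNC_SLNave        SLN_ave * f, LAI unchanged -> TNC scaled by f
TNC_LAIcan        LAI * f, SLN_ave unchanged -> TNC scaled by f
================  ========================================================

The exact-conservation rule divides by the factor (TNC held constant to
machine precision); the literal reading "decrease the other one by 20%"
(multiply by 2 - f) is available behind ``literal_compensation=True`` for
sensitivity checks, at the price of a small TNC drift (-4% at f=1.2).
SLN_top and SLN_ratio_top are always re-derived from (SLN_ave, KN), so KN
is untouched unless it is itself the target.
"""
from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .canopy import CanopyState, daily_canopy_assimilation
from .diurnal import DailyWeather
from .fvcb import DEFAULT_KINETICS, KineticConstants

TARGETS = ("beta", "gm", "Vcmax", "Jmax", "KN",
           "SLN_ave", "LAI_can", "TNC_SLNave", "TNC_LAIcan")

_SINGLE_FIELD = {"beta": "leaf_inclination", "gm": "gm25",
                 "Vcmax": "chi_v", "Jmax": "chi_j", "KN": "kn"}


@dataclass(frozen=True)
class ScenarioSpec:
    """One perturbation: which target, enhance or substitute, by how much."""

    target: str
    mode: str = "enhance"
    factor: float = 1.2
    donor: Optional[str] = None

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}; one of {TARGETS}")
        if self.mode not in ("enhance", "substitute"):
            raise ValueError("mode must be 'enhance' or 'substitute'")
        if self.factor <= 0:
            raise ValueError("factor must be > 0")
        if (self.mode == "substitute") != (self.donor is not None):
            raise ValueError("donor required iff mode == 'substitute'")


@dataclass(frozen=True)
class ScenarioResult:
    """Base vs perturbed AM_DAY with a field-level audit trail."""

    name: str
    target: str
    mode: str
    am_base: float
    am_new: float
    pct_change: float
    applied_state: CanopyState
    audit: tuple


def target_value(state: CanopyState, target: str) -> float:
    """The scalar a target refers to (TNC for the TNC_* composites)."""
    if target in _SINGLE_FIELD:
        return getattr(state, _SINGLE_FIELD[target])
    if target == "SLN_ave":
        return state.sln_ave
    if target == "LAI_can":
        return state.lai
    if target in ("TNC_SLNave", "TNC_LAIcan"):
        return state.tnc
    raise ValueError(f"unknown target {target!r}")


def apply_enhancement(state: CanopyState,
                      spec: Union[ScenarioSpec, str],
                      factor: Optional[float] = None,
                      literal_compensation: bool = False) -> CanopyState:
    """Return a new state with one target scaled; the input is untouched."""
    if isinstance(spec, ScenarioSpec):
        target, f = spec.target, spec.factor
    else:
        target, f = spec, (1.2 if factor is None else factor)
    if f <= 0:
        raise ValueError("factor must be > 0")
    comp = (2.0 - f) if literal_compensation else (1.0 / f)
    if target in _SINGLE_FIELD:
        field_name = _SINGLE_FIELD[target]
        return replace(state, **{field_name: getattr(state, field_name) * f})
    if target == "SLN_ave":
        return replace(state, sln_ave=state.sln_ave * f, lai=state.lai * comp)
    if target == "LAI_can":
        return replace(state, lai=state.lai * f, sln_ave=state.sln_ave * comp)
    if target == "TNC_SLNave":
        return replace(state, sln_ave=state.sln_ave * f)
    if target == "TNC_LAIcan":
        return replace(state, lai=state.lai * f)
    raise ValueError(f"unknown target {target!r}")


def apply_substitution(recipient: CanopyState, donor: CanopyState,
                       spec: Union[ScenarioSpec, str]) -> CanopyState:
    """Set the recipient's target to the donor's value (conservation rules
    as in :func:`apply_enhancement`, via factor = donor/recipient)."""
    target = spec.target if isinstance(spec, ScenarioSpec) else spec
    dv = target_value(donor, target)
    rv = target_value(recipient, target)
    if rv == 0:
        raise ValueError(f"recipient value for {target} is zero")
    return apply_enhancement(recipient, target, factor=dv / rv)


def _audit(old: CanopyState, new: CanopyState) -> tuple:
    changed = []
    for f in fields(CanopyState):
        a, b = getattr(old, f.name), getattr(new, f.name)
        if a != b:
            changed.append((f.name, a, b))
    return tuple(changed)


def run_scenario_suite(
    states: Mapping[str, CanopyState],
    weather: Union[DailyWeather, Mapping[str, DailyWeather]],
    specs: Sequence[Union[ScenarioSpec, str]],
    donors: Optional[Mapping[str, CanopyState]] = None,
    kin: KineticConstants = DEFAULT_KINETICS,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Cross every state with every spec; one row per (state, scenario).

    ``weather`` may be shared or a per-state mapping.  Substitution specs
    name their donor, looked up in ``donors``.  AM_base is computed once per
    state; results are deterministic and independent of mapping order.
    """
    if not states:
        raise ValueError("need at least one state")
    specs = [ScenarioSpec(target=s) if isinstance(s, str) else s for s in specs]
    if not specs:
        raise ValueError("need at least one scenario spec")
    rows = []
    for name in sorted(states):
        state = states[name]
        wx = weather[name] if isinstance(weather, Mapping) else weather
        am_base = daily_canopy_assimilation(state, wx, kin, dt).am_day
        for spec in specs:
            try:
                if spec.mode == "substitute":
                    if donors is None or spec.donor not in donors:
                        raise ValueError(f"donor {spec.donor!r} not provided")
                    new_state = apply_substitution(state, donors[spec.donor], spec)
                else:
                    new_state = apply_enhancement(state, spec)
                am_new = daily_canopy_assimilation(new_state, wx, kin, dt).am_day
            except Exception as exc:
                raise RuntimeError(
                    f"scenario {spec.target!r} failed for {name!r}") from exc
            rows.append({
                "name": name, "target": spec.target, "mode": spec.mode,
                "factor": spec.factor, "donor": spec.donor,
                "am_base": am_base, "am_new": am_new,
                "pct_change": 100.0 * (am_new - am_base) / am_base,
                "tnc_base": state.tnc, "tnc_new": new_state.tnc,
            })
    return pd.DataFrame(rows)
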