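"""Synthetic inputs for every stage of the pipeline.

Everything the estimation chain and canopy model consume can be generated
here, model-consistently and reproducibly:

* A/Ci curves with matched fluorescence, produced by the forward FvCB model
  along the standard instrument CO2 sequence, with PSII efficiency
  back-computed from the realised (A, Cc) — fluorescence tracks realised
  linear electron flow, so the variable-J inversion is exact at every point
  when noise is zero;
* low-O2 (non-photorespiratory) light-response curves for the alpha*beta /
  Rd calibration;
* single-day weather records for a subtropical rice site;
* a four-cultivar x two-stage trial fixture (two "super hybrid" cultivars,
  YLY3218 and YLY5867, against two inbred controls, ZD11 and NJ9108) whose
  leaf parameter magnitudes follow the published cultivar means, with
  canopy descriptors tagged by provenance.

All generators are pure functions of their arguments and ``seed``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .canopy import SLN_B_DEFAULT, CanopyState
from .diurnal import DailyWeather, solar_position
from .estimation import GasExchangeRecord
from .fvcb import (
    MEASUREMENT_KINETICS,
    EffectiveKinetics,
    LeafPhotoParams,
    j_light_response,
    measured_leaf_to_reference,
    solve_coupled_assimilation,
)

#: instrument CO2 sequence: stepped down 400 -> 100 then up 100 -> 1000
#: (400 and 100 each measured twice), 13 points
ACI_CA_SEQUENCE = (400.0, 300.0, 250.0, 200.0, 100.0,
                   100.0, 400.0, 450.0, 500.0, 550.0, 650.0, 800.0, 1000.0)

#: light levels of the low-O2 calibration curve, umol m-2 s-1
LOW_O2_PPFD_LEVELS = (200.0, 150.0, 75.0, 50.0, 30.0)

SITE_LATITUDE = 32.44        # deg N, subtropical paddy site
DOY_TILLERING = 207          # late July
DOY_FLOWERING = 245          # early September

CULTIVARS = ("YLY3218", "YLY5867", "ZD11", "NJ9108")
HYBRID_CULTIVARS = ("YLY3218", "YLY5867")
INBRED_CULTIVARS = ("ZD11", "NJ9108")
STAGES = ("tillering", "flowering")


@dataclass(frozen=True)
class SyntheticConfig:
    """Truth parameters and instrument settings for curve synthesis.

    ``truth`` carries the generating FvCB capacities on the same
    reference-normalised basis the estimation chain fits (see
    :data:`canophot.fvcb.MEASUREMENT_KINETICS`).  Fluorescence is emitted as
    an (Fs, Fm') pair consistent with the generating PhiPSII; only the
    ratio is information-bearing.
    """

    truth: LeafPhotoParams
    noise_sd_A: float = 0.0          # umol m-2 s-1, Gaussian on A
    noise_sd_fluor: float = 0.0      # relative, on Fs and Fm' independently
    seed: Optional[int] = None
    ppfd: float = 1500.0             # saturating measurement light
    tleaf: float = 35.0              # C
    gs: float = 0.5                  # mol H2O m-2 s-1, held per curve
    fm_ref: float = 2400.0           # plausible Fm' scale at saturating light
    kin: EffectiveKinetics = MEASUREMENT_KINETICS

    def __post_init__(self) -> None:
        if self.noise_sd_A < 0 or self.noise_sd_fluor < 0:
            raise ValueError("noise must be >= 0")


def _rng(seed: Optional[int]) -> np.random.Generator:
    return np.random.default_rng(seed)


def synth_aci_curve(cfg: SyntheticConfig) -> list[GasExchangeRecord]:
    """Forward-model A/Ci curve with matched fluorescence.

    For each Ca in the instrument sequence the coupled model is solved with
    the truth parameters and constant stomatal conductance; PhiPSII is set
    so the fluorescence-based J reproduces the realised electron demand
    (A + Rd)(4 Cc + 8 G*)/(Cc - G*), making the record set exactly
    invertible by the variable-J chain at zero noise.
    """
    t = cfg.truth
    rng = _rng(cfg.seed)
    j_pot = j_light_response(cfg.ppfd, t.Jmax25, t.theta, eff=t.alphabeta)
    g = cfg.kin.gamma_star
    records = []
    for ca in ACI_CA_SEQUENCE:
        sol = solve_coupled_assimilation(
            ca, Vcmax=t.Vcmax25, J=j_pot, Rd=t.Rd25, TPU=t.TPU25,
            gm=t.gm25, kin=cfg.kin, gs=cfg.gs)
        if sol.Ci <= 0:
            raise RuntimeError(f"truth parameters give Ci <= 0 at Ca={ca}")
        j_flu = (sol.A + t.Rd25) * (4.0 * sol.Cc + 8.0 * g) / (sol.Cc - g)
        phi = j_flu / (t.alphabeta * cfg.ppfd)
        if not 0 < phi < 1:
            raise RuntimeError(f"implied PhiPSII={phi:.3f} out of range at Ca={ca}")
        fm = cfg.fm_ref * (1.0 + cfg.noise_sd_fluor * rng.standard_normal())
        fs = fm * (1.0 - phi) * (1.0 + cfg.noise_sd_fluor * rng.standard_normal())
        a_obs = sol.A + cfg.noise_sd_A * rng.standard_normal()
        records.append(GasExchangeRecord(
            A=a_obs, Ca=ca, Ci=sol.Ci, gs=cfg.gs, PPFD=cfg.ppfd,
            Tleaf=cfg.tleaf, Fs=fs, Fm_prime=fm, O2_percent=21.0))
    return records


def synth_low_o2_light_response(cfg: SyntheticConfig) -> list[GasExchangeRecord]:
    """Five-point light response at 2% O2 for the alpha*beta/Rd calibration.

    Non-photorespiratory identity: A = alphabeta * (PhiPSII * PPFD) / 4 - Rd.
    PhiPSII follows a plausible gently declining light dependence; any such
    profile leaves the calibration regression exact at zero noise.
    """
    t = cfg.truth
    rng = _rng(cfg.seed)
    records = []
    for ppfd in LOW_O2_PPFD_LEVELS:
        phi = 0.80 - 0.00045 * ppfd
        a_true = t.alphabeta * phi * ppfd / 4.0 - t.Rd25
        fm = cfg.fm_ref * (1.2 + 0.3 * (1.0 - ppfd / 200.0))
        fm *= 1.0 + cfg.noise_sd_fluor * rng.standard_normal()
        fs = fm * (1.0 - phi) * (1.0 + cfg.noise_sd_fluor * rng.standard_normal())
        a_obs = a_true + cfg.noise_sd_A * rng.standard_normal()
        ca = 400.0
        records.append(GasExchangeRecord(
            A=a_obs, Ca=ca, Ci=0.8 * ca, gs=0.2, PPFD=ppfd, Tleaf=cfg.tleaf,
            Fs=fs, Fm_prime=fm, O2_percent=2.0))
    return records


#: daily global radiation as a fraction of the extraterrestrial total:
#: 'typical' matches monsoon-season climate normals for the lower-Yangtze
#: rice belt (~16-18 MJ m-2 d-1 in July), 'clear' is a cloudless day.
_RADIATION_FRACTION = {"clear": 0.65, "typical": 0.45, "overcast": 0.28}


def extraterrestrial_radiation(latitude: float, day_of_year: int) -> float:
    """Daily extraterrestrial solar radiation, MJ m-2 d-1 (FAO-56 form)."""
    decl = solar_position(latitude, day_of_year, 12.0)[0]
    phi, delta = math.radians(latitude), math.radians(decl)
    ws = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(delta))))
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / 365.0)
    return (24.0 * 60.0 / math.pi) * 0.0820 * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws))


def synth_weather_day(latitude: float = SITE_LATITUDE,
                      day_of_year: int = DOY_TILLERING,
                      profile: str = "typical",
                      seed: Optional[int] = None) -> DailyWeather:
    """A plausible rice-season weather day at a subtropical site.

    ``profile`` scales the extraterrestrial daily total ('clear' ~65%,
    'typical' ~45%, 'overcast' ~28%), clipped to the realistic
    8-28 MJ m-2 d-1 band.  Temperatures follow a smooth seasonal
    climatology peaking in late July.  With a seed, small Gaussian jitter
    is added to radiation (sd 1 MJ) and temperatures (sd 0.5 C); without
    one the output is the deterministic profile value.
    """
    if profile not in _RADIATION_FRACTION:
        raise ValueError(f"profile must be one of {sorted(_RADIATION_FRACTION)}")
    ra = extraterrestrial_radiation(latitude, day_of_year)
    radiation = min(max(ra * _RADIATION_FRACTION[profile], 8.0), 28.0)
    warm = math.cos(2.0 * math.pi * (day_of_year - 205) / 365.0)
    tmax = 26.5 + 7.0 * warm - (3.0 if profile == "overcast" else 0.0)
    tmin = 19.5 + 6.5 * warm - (1.0 if profile == "overcast" else 0.0)
    rh = 85.0 if profile == "overcast" else 70.0
    if seed is not None:
        rng = _rng(seed)
        radiation = float(np.clip(radiation + rng.normal(0.0, 1.0), 8.0, 28.0))
        tmax += float(rng.normal(0.0, 0.5))
        tmin = min(tmin + float(rng.normal(0.0, 0.5)), tmax)
    return DailyWeather(latitude=latitude, day_of_year=day_of_year,
                        radiation_daily=radiation, Tmax=tmax, Tmin=tmin, rh=rh)


# ---------------------------------------------------------------------------
# trial fixture
# ---------------------------------------------------------------------------

#: cultivar leaf means (Vcmax, Jmax, TPU, gm) by stage, on the measurement
#: scale of the fitting protocol (35 C leaf, reference-constant kinetics)
_LEAF_MEANS = {
    ("YLY3218", "tillering"): (140.4, 214.7, 12.3, 0.250),
    ("YLY5867", "tillering"): (152.3, 185.2, 11.4, 0.180),
    ("ZD11", "tillering"): (90.0, 156.8, 9.08, 0.136),
    ("NJ9108", "tillering"): (91.9, 155.0, 9.41, 0.154),
    ("YLY3218", "flowering"): (141.1, 221.7, 13.3, 0.287),
    ("YLY5867", "flowering"): (122.3, 192.1, 11.8, 0.318),
    ("ZD11", "flowering"): (113.2, 216.4, 12.8, 0.231),
    ("NJ9108", "flowering"): (95.2, 174.3, 11.4, 0.145),
}

#: canopy descriptors (lai, sln_ave, inclination deg, kn) — plausible values
#: reproducing the reported qualitative ordering (hybrids ~15% higher LAI;
#: inbred lines the most erect; SLN_ave equal across cultivars at tillering,
#: higher in the inbreds at flowering); not printed numerically in the
#: source tables.
_CANOPY_ASSUMED = {
    ("YLY3218", "tillering"): (5.8, 1.55, 58.0, 0.4),
    ("YLY5867", "tillering"): (5.6, 1.55, 63.0, 0.4),
    ("ZD11", "tillering"): (4.9, 1.55, 66.0, 0.4),
    ("NJ9108", "tillering"): (4.8, 1.55, 65.0, 0.4),
    ("YLY3218", "flowering"): (6.8, 1.40, 52.0, 0.4),
    ("YLY5867", "flowering"): (6.6, 1.38, 57.0, 0.4),
    ("ZD11", "flowering"): (5.7, 1.60, 60.0, 0.4),
    ("NJ9108", "flowering"): (5.6, 1.70, 59.0, 0.4),
}


@dataclass(frozen=True)
class TrialEntry:
    """One cultivar-by-stage fixture member.

    ``measured`` carries the leaf capacities on the measurement scale (as
    the estimation chain fits them); ``leaf`` holds the same capacities
    referred to 25 C through the inverse Arrhenius step, which is what the
    canopy model consumes.
    """

    cultivar: str
    stage: str
    leaf: LeafPhotoParams
    canopy: CanopyState
    measured: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def synth_trial_fixture(seed: int = 0,
                        rd_frac: float = 0.015,
                        sln_b: float = SLN_B_DEFAULT,
                        t_meas: float = 35.0) -> dict:
    """Four cultivars x two stages of (leaf params, canopy state).

    Leaf capacities sit at the published cultivar means on the measurement
    scale (provenance ``measured-mean``) and are referred to 25 C via
    :func:`canophot.fvcb.measured_leaf_to_reference` before entering the
    canopy state; canopy descriptors are documented plausible values
    (provenance ``assumed``).  Deterministic: the same seed always returns
    an identical fixture (the descriptors are fixed, not sampled).
    """
    out = {}
    for (cultivar, stage), (vc, jm, tpu, gm) in _LEAF_MEANS.items():
        lai, sln, beta, kn = _CANOPY_ASSUMED[(cultivar, stage)]
        leaf = measured_leaf_to_reference(vc, jm, tpu, gm,
                                          T_meas=t_meas, rd_frac=rd_frac)
        canopy = CanopyState.from_leaf(
            leaf, lai=lai, sln_ave=sln, kn=kn, leaf_inclination=beta,
            sln_b=sln_b, rd_frac=rd_frac)
        prov = {"Vcmax": "measured-mean", "Jmax": "measured-mean",
                "TPU": "measured-mean", "gm": "measured-mean",
                "Rd25": "derived:rd_frac*Vcmax25",
                "leaf": f"inverse-Arrhenius from {t_meas} C measurement scale",
                "lai": "assumed", "sln_ave": "assumed",
                "leaf_inclination": "assumed", "kn": "assumed"}
        out[(cultivar, stage)] = TrialEntry(
            cultivar=cultivar, stage=stage, leaf=leaf, canopy=canopy,
            measured={"Vcmax": vc, "Jmax": jm, "TPU": tpu, "gm": gm},
            provenance=prov)
    return out


def stage_weather(stage: str, profile: str = "typical",
                  seed: Optional[int] = None) -> DailyWeather:
    """Representative measurement-campaign weather day for a stage."""
    doy = DOY_TILLERING if stage == "tillering" else DOY_FLOWERING
    return synth_weather_day(SITE_LATITUDE, doy, profile, seed)
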