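"""Tests for the sunlit/shaded two-leaf canopy model."""
import dataclasses
import math

import numpy as np
import pytest

import canophot as cp
from canophot.canopy import ellipsoidal_x
from canophot.multilayer import daily_canopy_assimilation_multilayer


def _state(**kw):
    base = dict(lai=5.0, sln_ave=1.55, kn=0.4, leaf_inclination=60.0,
                chi_v=40.0, chi_j=75.0, gm25=0.13)
    base.update(kw)
    return cp.CanopyState(**base)


def _weather(**kw):
    base = dict(latitude=32.44, day_of_year=207, radiation_daily=18.0,
                Tmax=33.5, Tmin=26.0, rh=70.0)
    base.update(kw)
    return cp.DailyWeather(**base)


class TestExtinction:
    def test_spherical_distribution_matches_closed_form(self):
        # x = 1 at mean angle ~56 deg; kb ~ 0.5 / sin(elevation)
        incl = math.degrees(9.65 * 4.0 ** -1.65)  # mean angle for x = 1
        kb, _ = cp.extinction_coefficients(incl, 30.0)
        assert kb == pytest.approx(0.5 / math.sin(math.radians(30.0)), rel=0.01)

    def test_horizontal_leaves_project_fully(self):
        kb, _ = cp.extinction_coefficients(1.0, 30.0)
        assert kb == pytest.approx(1.0, abs=0.01)

    def test_kb_decreasing_in_elevation(self):
        kbs = [cp.extinction_coefficients(60.0, e)[0]
               for e in np.linspace(5.0, 89.0, 40)]
        assert np.all(np.diff(kbs) <= 1e-12)

    def test_no_beam_below_horizon(self):
        kb, kd = cp.extinction_coefficients(60.0, -5.0)
        assert kb is None and kd == 0.78

    def test_x_monotone_with_erectness(self):
        assert ellipsoidal_x(10.0) > ellipsoidal_x(50.0) > ellipsoidal_x(85.0)


class TestSunlitPartition:
    def test_small_kb_limit(self):
        lai_sun, _ = cp.sunlit_partition(4.0, 1e-9)
        assert lai_sun == pytest.approx(4.0, rel=1e-6)

    def test_hand_evaluated_split(self):
        lai_sun, lai_shade = cp.sunlit_partition(4.0, 0.5)
        assert lai_sun == pytest.approx(1.7293, abs=1e-4)
        assert lai_shade == pytest.approx(2.2707, abs=1e-4)

    def test_conservation(self):
        for kb in (0.2, 0.5, 1.1):
            s, h = cp.sunlit_partition(6.3, kb)
            assert s + h == pytest.approx(6.3, abs=1e-12)
            assert s >= 0 and h >= 0


class TestAbsorbedPar:
    def test_dark_absorbs_nothing(self):
        assert cp.absorbed_par(0.0, 0.0, 0.7, 0.78, 5.0) == (0.0, 0.0)

    def test_diffuse_only_sunlit_share_is_depth_weighted(self):
        i_sun, i_shade = cp.absorbed_par(0.0, 400.0, 0.7, 0.78, 5.0)
        kd_p = 0.78 * math.sqrt(0.85)
        expect = 400.0 * (1 - 0.036) * kd_p / (kd_p + 0.7) * (
            1 - math.exp(-(kd_p + 0.7) * 5.0))
        assert i_sun == pytest.approx(expect)
        assert i_shade > 0

    def test_absorption_bounded_by_incident(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            ib, idf = rng.uniform(0, 2000), rng.uniform(0, 800)
            kb = rng.uniform(0.2, 1.5)
            lai = rng.uniform(0.5, 8.0)
            i_sun, i_shade = cp.absorbed_par(ib, idf, kb, 0.78, lai)
            assert i_sun >= 0 and i_shade >= 0
            assert i_sun + i_shade <= ib + idf + 1e-9

    def test_matches_multilayer_flux_bookkeeping(self):
        """Two-leaf absorbed fluxes equal the depth integrals they summarise."""
        from canophot.multilayer import _leaf_area_absorption
        ib, idf, kb, kd, lai, sigma = 1200.0, 350.0, 0.65, 0.78, 5.2, 0.15
        i_sun, i_shade = cp.absorbed_par(ib, idf, kb, kd, lai, sigma)
        n = 4000
        dl = lai / n
        num_sun = num_tot = 0.0
        for i in range(n):
            ell = (i + 0.5) * dl
            q_beam, q_shared = _leaf_area_absorption(ell, ib, idf, kb, kd, sigma)
            f_sun = math.exp(-kb * ell)
            num_sun += (q_shared * f_sun + q_beam * f_sun) * dl
            num_tot += (q_shared + q_beam * f_sun) * dl
        assert i_sun == pytest.approx(num_sun, rel=2e-3)
        assert i_sun + i_shade == pytest.approx(num_tot, rel=2e-3)


class TestNitrogenProfile:
    def test_uniform_profile_at_zero_kn(self):
        p = cp.nitrogen_profile(1.6, 0.0, 5.0, 0.6)
        assert p.sln_top == pytest.approx(1.6)
        assert p.sln_ratio_top == pytest.approx(1.0)

    def test_hand_evaluated_sln_top(self):
        assert cp.sln_top_from_ave(1.6, 0.4) == pytest.approx(1.9413, abs=1e-3)

    def test_nitrogen_conserved_exactly(self):
        for kn, kb in [(0.0, 0.4), (0.4, 0.7), (1.2, 1.1)]:
            p = cp.nitrogen_profile(1.55, kn, 5.8, kb)
            assert p.n_sun + p.n_shade == pytest.approx(1.55 * 5.8, abs=1e-9)
            assert p.sln_ratio_top <= 1.0 + 1e-12


class TestCapacity:
    def test_chi_derivation_is_a_ratio(self):
        leaf = cp.LeafPhotoParams(Vcmax25=100.0, Jmax25=160.0, TPU25=10.0,
                                  Rd25=1.0, gm25=0.2)
        st = cp.CanopyState.from_leaf(leaf, lai=5.0, sln_ave=1.6, kn=0.0,
                                      leaf_inclination=60.0, sln_b=0.0)
        assert st.chi_v == pytest.approx(100.0 / 1.6)  # = 62.5 umol / g N / s

    def test_proportional_to_nitrogen_when_unstructured(self):
        p = cp.nitrogen_profile(1.55, 0.4, 5.0, 0.7)
        caps = cp.capacity_from_nitrogen(p, 60.0, 110.0, 2.0, 3.0, sln_b=0.0)
        assert caps["vcmax25_sun"] / caps["vcmax25_shade"] == pytest.approx(
            p.n_sun / p.n_shade)

    def test_floor_at_zero_with_warning(self):
        p = cp.nitrogen_profile(0.2, 0.0, 5.0, 0.7)
        with pytest.warns(UserWarning):
            caps = cp.capacity_from_nitrogen(p, 60.0, 110.0, 2.0, 3.0, sln_b=0.5)
        assert caps["vcmax25_sun"] == 0.0


class TestHourlyCanopy:
    def _env(self, par_dir=1200.0, par_dif=350.0, elev=55.0, ta=30.0):
        return cp.HourlyEnvironment(hour=12.5, PAR_direct=par_dir,
                                    PAR_diffuse=par_dif, Ta=ta, VPD=1.5,
                                    solar_elevation=elev, Ca=400.0)

    def test_night_is_respiration_only(self):
        res = cp.canopy_hourly_assimilation(self._env(0.0, 0.0, -10.0), _state())
        assert res["A_sun"] + res["A_shade"] <= 0.0

    def test_doubling_light_never_decreases_assimilation(self):
        st = _state()
        a1 = cp.canopy_hourly_assimilation(self._env(600.0, 150.0), st)
        a2 = cp.canopy_hourly_assimilation(self._env(1200.0, 300.0), st)
        assert (a2["A_sun"] + a2["A_shade"]) >= (a1["A_sun"] + a1["A_shade"]) - 1e-9

    def test_proportional_split_homogeneity(self):
        """The coupled big-leaf response is 1-homogeneous: splitting light,
        capacities and gm into proportional shares conserves total A."""
        kin = cp.DEFAULT_KINETICS
        env = self._env()
        kin_eff = kin.at(env.Ta)

        def leaf_a(i_abs, vc25, jm25, gm_scale):
            vc = cp.arrhenius_response(vc25, kin.Ea_Vcmax, env.Ta)
            jm = cp.arrhenius_response(jm25, kin.Ea_Jmax, env.Ta)
            rd = cp.arrhenius_response(0.015 * vc25, kin.Ea_Rd, env.Ta)
            j = cp.j_light_response(i_abs, jm, 0.7, eff=0.5)
            return cp.solve_coupled_assimilation(
                400.0, Vcmax=vc, J=j, Rd=rd, TPU=None,
                gm=0.13 * gm_scale, kin=kin_eff, ci_ratio=0.7).A

        whole = leaf_a(900.0, 300.0, 550.0, 5.0)
        for f in (0.3, 0.5, 0.8):
            parts = (leaf_a(900.0 * f, 300.0 * f, 550.0 * f, 5.0 * f)
                     + leaf_a(900.0 * (1 - f), 300.0 * (1 - f),
                              550.0 * (1 - f), 5.0 * (1 - f)))
            assert parts == pytest.approx(whole, rel=1e-9)

    def test_sunlit_fraction_matches_layer_resolved_aggregate(self):
        """The sunlit big leaf is near-exact: all sunlit leaves share the
        dominant beam, so aggregation loses almost nothing (<1%)."""
        from canophot.multilayer import _leaf_area_absorption
        from canophot.canopy import extinction_coefficients, sln_top_from_ave
        kin = cp.DEFAULT_KINETICS
        env = self._env()
        for st in (_state(), _state(kn=0.0, lai=6.5),
                   _state(leaf_inclination=45.0, chi_j=95.0)):
            res = cp.canopy_hourly_assimilation(env, st, kin)
            kb, kd = extinction_coefficients(st.leaf_inclination,
                                             env.solar_elevation, st.kd)
            kin_eff = kin.at(env.Ta)
            gm_leaf = cp.arrhenius_response(st.gm25, kin.Ea_gm, env.Ta)
            top = sln_top_from_ave(st.sln_ave, st.kn)
            n, a_sun = 400, 0.0
            dl = st.lai / n
            for i in range(n):
                ell = (i + 0.5) * dl
                sln = top * math.exp(-st.kn * ell / st.lai)
                vc25 = st.chi_v * max(sln - st.sln_b, 0.0)
                jm25 = st.chi_j * max(sln - st.sln_b, 0.0)
                vc = cp.arrhenius_response(vc25, kin.Ea_Vcmax, env.Ta)
                jm = cp.arrhenius_response(jm25, kin.Ea_Jmax, env.Ta)
                rd = cp.arrhenius_response(0.015 * vc25, kin.Ea_Rd, env.Ta)
                qb, qs = _leaf_area_absorption(ell, env.PAR_direct,
                                               env.PAR_diffuse, kb, kd, st.sigma)
                j = cp.j_light_response(qb + qs, jm, st.theta, eff=st.psii_eff)
                sol = cp.solve_coupled_assimilation(
                    env.Ca, Vcmax=vc, J=j, Rd=rd, TPU=None, gm=gm_leaf,
                    kin=kin_eff, ci_ratio=st.ci_ratio)
                a_sun += math.exp(-kb * ell) * sol.A * dl
            assert res["A_sun"] == pytest.approx(a_sun, rel=0.01)

    def test_two_leaf_bounds_multilayer_from_above(self, tillering_weather):
        """Within-shade light heterogeneity plus the concave NRH response
        means the shaded big leaf can only overestimate the layer-resolved
        canopy (Jensen's inequality); the daily gap stays inside a
        documented envelope."""
        rng = np.random.default_rng(21)
        for _ in range(6):
            st = _state(lai=float(rng.uniform(3.0, 7.0)),
                        sln_ave=float(rng.uniform(1.1, 1.9)),
                        kn=float(rng.uniform(0.0, 0.8)),
                        leaf_inclination=float(rng.uniform(40.0, 75.0)),
                        chi_v=float(rng.uniform(25.0, 55.0)),
                        chi_j=float(rng.uniform(50.0, 100.0)),
                        gm25=float(rng.uniform(0.07, 0.17)))
            two = cp.daily_canopy_assimilation(st, tillering_weather).a_can_day
            ref = daily_canopy_assimilation_multilayer(st, tillering_weather)
            assert ref - 1e-9 <= two <= 1.25 * ref


class TestDailyCanopy:
    def test_zero_radiation_day_is_net_negative(self):
        res = cp.daily_canopy_assimilation(_state(), _weather(radiation_daily=0.0))
        assert res.a_can_day <= 0.0

    def test_halving_lai_uniform_n_reduces_assimilation(self):
        bright = _weather(radiation_daily=24.0)
        full = cp.daily_canopy_assimilation(_state(kn=0.0), bright)
        half = cp.daily_canopy_assimilation(_state(kn=0.0, lai=2.5), bright)
        assert half.a_can_day < full.a_can_day

    def test_time_step_refinement_within_one_percent(self):
        st, wx = _state(), _weather()
        hourly = cp.daily_canopy_assimilation(st, wx, dt=1.0).a_can_day
        half = cp.daily_canopy_assimilation(st, wx, dt=0.5).a_can_day
        assert hourly == pytest.approx(half, rel=0.01)

    def test_nondecreasing_in_canopy_nitrogen(self):
        wx = _weather()
        values = [cp.daily_canopy_assimilation(_state(sln_ave=s), wx).a_can_day
                  for s in np.arange(0.8, 2.51, 0.1)]
        assert np.all(np.diff(values) >= -1e-9)

    def test_trace_is_daylight_only(self):
        res = cp.daily_canopy_assimilation(_state(), _weather())
        assert len(res.trace) < 24
        assert (res.trace["PAR_direct"] + res.trace["PAR_diffuse"]).iloc[0] >= 0


class TestAmDay:
    def test_zero(self):
        assert cp.am_day(0.0) == 0.0

    def test_exact_product_rule(self):
        assert cp.am_day(1.3) == 1.3 * cp.AM_DAY_FACTOR
        assert cp.AM_DAY_FACTOR == pytest.approx(44.0 * 0.41 * 0.85)
        assert cp.am_day(1.3) == pytest.approx(19.9342)

    def test_fixture_magnitudes_in_reported_band(self, trial_fixture,
                                                 tillering_weather):
        for cv in cp.synthetic.CULTIVARS:
            res = cp.daily_canopy_assimilation(
                trial_fixture[(cv, "tillering")].canopy, tillering_weather)
            assert 15.0 <= res.am_day <= 25.0
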