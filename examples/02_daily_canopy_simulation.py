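"""Simulate one day of canopy photosynthesis for the cultivar fixture.

Takes the four-cultivar trial fixture (two super hybrid lines, two inbred
controls), builds a typical tillering-stage weather day for the subtropical
rice site, and integrates the sunlit/shaded two-leaf model from sunrise to
sunset to the daily aboveground biomass increment AM_DAY.
"""
import canophot as cp
from canophot.synthetic import CULTIVARS

fixture = cp.synth_trial_fixture()
weather = cp.stage_weather("tillering")
print(f"weather: DOY {weather.day_of_year}, {weather.radiation_daily:.1f} "
      f"MJ m-2 d-1, {weather.Tmin:.1f}-{weather.Tmax:.1f} C\n")

print(f"{'cultivar':10s} {'A_can,day':>10s} {'AM_DAY':>8s}")
for cv in CULTIVARS:
    res = cp.daily_canopy_assimilation(fixture[(cv, "tillering")].canopy,
                                       weather)
    print(f"{cv:10s} {res.a_can_day:10.3f} {res.am_day:8.2f}")
print("\nA_can,day in mol CO2 m-2 ground d-1; AM_DAY in g biomass m-2 d-1")
print("(= A_can,day * 44 * 0.41 * 0.85). The hybrid cultivars fix more")
print("carbon than the inbred controls at tillering, mirroring their")
print("higher Jmax and gm and larger leaf area index.")

trace = cp.daily_canopy_assimilation(
    fixture[("YLY3218", "tillering")].canopy, weather).trace
peak = trace.loc[trace["A_total"].idxmax()]
print(f"\nYLY3218 peak hour {peak.hour:.1f}: sunlit {peak.A_sun:.1f} + "
      f"shaded {peak.A_shade:.1f} = {peak.A_total:.1f} umol CO2 m-2 s-1")
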