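"""Growing seasons, thermal sums and between-survey climate change.

Simulates four decades of daily weather for one site, detects each
year's growing season with the 10-day/+5 C window rule, accumulates
degree-days, and converts the OLS trend into a between-survey delta.
"""

from resurvey import SimulationTruth, annual_climate, gen_climate, trend_delta
from resurvey.climate import growing_season, thermal_sum

truth = SimulationTruth(seed=0)
daily = gen_climate(truth, "NBs-fertile", n_years=43, seed=5, year0=1971)

one_year = daily[daily["date"].dt.year == 1971]
season = growing_season(one_year["tmean_c"].to_numpy())
gdd = thermal_sum(one_year["tmean_c"].to_numpy(), season)
print(f"1971: growing season days {season[0]}-{season[1]}, "
      f"thermal sum {gdd:.0f} degree-days above +5 C")

annual = annual_climate(daily)
gdd_trend = trend_delta(annual["gdd"], annual["year"], 1971, 2013)
prec_trend = trend_delta(annual["prec"], annual["year"], 1971, 2013)
print(f"thermal-sum trend {gdd_trend['slope']:.2f} Cd/yr "
      f"-> +{gdd_trend['delta']:.0f} Cd over {gdd_trend['years']} years")
print(f"precipitation trend {prec_trend['slope']:.2f} mm/yr "
      f"-> {prec_trend['delta']:+.0f} mm/yr over the survey interval")
print()
print("The delta is the regression slope times the interval length, so")
print("sites resurveyed after different intervals stay comparable.")
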