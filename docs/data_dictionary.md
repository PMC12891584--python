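# Data dictionary — site bundle CSV tables

All tables use a fixed 365-day calendar (Feb 29 dropped). Day-of-year (DOY)
values are 1-based: Jan 1 = 1, Dec 31 = 365. Missing values are empty cells
(NaN).

## daily_temperature.csv

| column | units | description |
|---|---|---|
| site_id | – | integer site identifier |
| year | – | calendar year |
| doy | – | 1-based day of year, 1..365 |
| temperature_c | °C | daily mean air temperature |

## annual_series.csv

| column | units | description |
|---|---|---|
| site_id | – | integer site identifier |
| latitude | degrees | site latitude (positive north) |
| year | – | calendar year |
| alan_nw | nW cm⁻² sr⁻¹ | annual nighttime-light radiance |
| lud_doy | DOY | leaf-unfolding date |
| gdp | currency | annual GDP |
| dfs_observed_doy | DOY | observed date of foliar senescence (NaN = missing) |
| mad_flagged | bool | (filtered table only) flagged as outlier by the MAD screen |

## monthly_climate.csv

| column | units | description |
|---|---|---|
| site_id | – | integer site identifier |
| year | – | calendar year |
| month | – | calendar month 1..12 |
| precip_mm | mm | monthly precipitation |
| shortwave_wm2 | W m⁻² | monthly mean shortwave radiation |

## manifest.txt

Key–value pairs: `n_sites`, `year_start`, `year_end`, `tables`.

## Notes on the synthetic generator

- Temperature = annual mean (lowered 0.6 °C per degree of latitude above
  45°) + seasonal cosine peaking near DOY 200 + linear warming trend
  (constant within each year) + AR(1) noise continuous across year
  boundaries with stationary sd `temp_noise_sd`.
- Annual radiance = `alan_start + alan_growth·t` + Gaussian noise, floored
  at 0.
- Observed DFS = process-model prediction + iid Gaussian noise rounded to
  whole days (an assumption — no distributional description of in-situ DFS
  noise is available); years without a threshold crossing are missing.
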