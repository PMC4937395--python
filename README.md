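# hazecrop

Severe haze over China's main crop belts dims the sunlight that rice and
wheat canopies receive. `hazecrop` is a reusable pipeline that quantifies
this chain for the four heavily polluted, heavily cultivated regions — the
North China Plain (NCP), Yangtze River Delta (YRD), central eastern China
(CEC) and Sichuan Basin (SCB): from monthly gridded aerosol optical depth
(AOD) fields, through surface solar irradiance, to regional and national
production losses. It is written for agro-environmental researchers who
want the whole chain testable and re-runnable on a desktop, without any
satellite download.

## The model chain

1. **AOD fields** — monthly 0.1° fields with regional hotspots (AOD
   0.4–0.8, winter-peaked), ~0.1 background and random retrieval gaps; a
   synthetic generator (`hazecrop.synthetic_data`) produces fields with
   this structure, seed-reproducibly.
2. **Processing** — block average to 0.5° using all unmasked fine cells;
   calendar-month and seasonal climatologies (`hazecrop.aod_processing`).
3. **Radiative transfer** — cloud-free surface spectral irradiance over
   300–750 nm from a delta-Eddington two-stream solver with multilayer
   adding (`hazecrop.radiative_transfer`): aerosol well-mixed in the
   boundary layer (single-scattering albedo ω₀ = 0.80, asymmetry g = 0.65,
   Ångström α = 1), Rayleigh scattering, ozone, surface albedo 0.2, daily
   means from a 24-node daylight quadrature.
4. **Solar reduction** — per cell and month, the percent reduction
   100·(E₀−E_a)/E₀ of daily global irradiance relative to the aerosol-free
   baseline; regional quartile statistics; growing-window means over the
   three months before harvest (`hazecrop.solar_reduction`).
5. **Crop impact** — linear yield response (percent yield loss =
   β · percent radiation loss, β calibrated per crop), diffuse-radiation
   sensitivity cases (effective radiation E_dir + k·E_dif, k ≥ 1),
   thick-cloud damping, and production-share aggregation to national
   percent and tonnage losses (`hazecrop.crop_impact`).

See `docs/methods.md` for assumptions, defaults and known limitations.

## Worked example

```python
import xarray as xr
from hazecrop import aod_processing, crop_impact, solar_reduction, synthetic_data
from hazecrop.config import DEFAULT_BETAS
from hazecrop.radiative_transfer import RTConfig
from hazecrop.regions import default_regions

# synthetic two-year monthly AOD record at 0.1 degrees, seed-reproducible
aod = synthetic_data.generate_aod_fields(synthetic_data.SyntheticAODConfig(seed=0))
coarse = aod_processing.regrid_block_average(aod, factor=5)      # -> 0.5 deg
clim = aod_processing.monthly_climatology(coarse)                # 12 mean fields

# irradiance reductions over the four region boxes (about a minute on one core)
regions = default_regions()
where = xr.concat([r.mask(clim.isel(month=0)) for r in regions], dim="r").any("r")
fields = solar_reduction.monthly_reduction_maps(clim, RTConfig(), where)

stats = solar_reduction.region_percentiles(fields, regions)
winter = stats[(stats.region == "ALL4") & (stats.season == "DJF")].iloc[0]
print(f"winter reduction IQR: {winter.q1:.1f}-{winter.q3:.1f}%")

table = synthetic_data.generate_production_table(seed=0)
models = {c: crop_impact.YieldResponseModel(c, b) for c, b in DEFAULT_BETAS.items()}
report = crop_impact.build_report(fields, table, models)
nat = report.national.set_index(["crop", "case"])
for crop in ("wheat", "rice"):
    base = nat.loc[(crop, "none")]
    high = nat.loc[(crop, "high")]
    print(f"{crop}: national loss {base.national_reduction_pct:.2f}% "
          f"({base.national_loss_tonnes:.2e} t), "
          f"high-diffuse case {high.national_reduction_pct:.2f}%")
```

Output (seed 0):

```
winter reduction IQR: 38.3-42.2%
wheat: national loss 8.23% (2.06e+07 t), high-diffuse case 4.30%
rice: national loss 2.15% (6.33e+06 t), high-diffuse case 1.01%
```

Reading it: winter hotspot AOD (0.52–1.04 after the seasonal peak) cuts
daily surface irradiance in the four regions by roughly 40% per cell.
Propagated through the growing windows and the calibrated yield responses,
the four regions' losses aggregate — via their 75% share of national wheat
and 45% of national rice production — to about an 8% national wheat loss
and 2% national rice loss; crediting diffuse light with higher
photosynthetic efficiency (high case, k = 1.5) roughly halves both.

The same chain is scriptable from the shell:

```sh
hazecrop synth-aod --seed 0 --out aod.nc
hazecrop regrid --factor 5 --in aod.nc --out coarse.nc
hazecrop climatology --in coarse.nc --out clim.nc
hazecrop reduce --in clim.nc --out reduction.nc --regions-only
hazecrop stats --in reduction.nc --out stats.csv
hazecrop synth-production --out production.csv
hazecrop impact --reduction reduction.nc --production production.csv --out-csv impact.csv
```

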