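# biometeokit

Human-biometeorology toolkit: auxiliary meteorological conversions, a
mean-radiant-temperature (Tmrt) simulation chain, and five rational
thermal-index engines — PMV, SET*, PET, mPET and UTCI — with a batch CLI
and a synthetic station-series generator for testing.

## What it computes

| Function | Inputs (fundamental) | Output |
| --- | --- | --- |
| `vp_rh_exchange` | Ta + one of VP/RH | the missing humidity variable |
| `wind_at_height` | wind speed + measurement height | speed at 1.1 m (or any height) |
| `tmrt_calc` | Ta, VP/RH, v, site (lon/lat/elev) + optional time, cloud, radiation knobs | Tmrt plus the 10 shortwave/longwave budget terms |
| `pmv_calc` | Ta, VP, v(1.1 m), Tmrt | {PMV, Teq, hclo} |
| `set_star` | Ta, RH, v(1.1 m), Tmrt | SET* (degC) |
| `pet_calc` | Ta, VP, v(1.1 m), Tmrt | PET + 10 physiological/flux fields |
| `mpet_calc` | Ta, VP, v(1.1 m), Tmrt | mPET + 13 fields (multi-node model, Ta-adaptive clothing) |
| `utci_calc` | Ta, VP, v(1.1 m or v10), Tmrt | UTCI (degC, operational polynomial) |

All engines take a `MeteoRecord` (wind at the 1.1 m anthropometric
height; humidity normalised through the Magnus saturation curve) and a
`SubjectProfile` (defaults: work 80 W, 1.75 m, 75 kg, 35 y, male,
standing; clothing 0.6 clo for PMV, 0.9 clo for SET*/PET/mPET, mPET
defaults to Ta-adaptive clothing).

## Library example

```python
from biometeokit import MeteoRecord, SubjectProfile, pet_calc, tmrt_calc

budget = tmrt_calc(Ta=20.0, RH=50.0, v=0.1,
                   longitude=121.5, latitude=23.5, sea_level_height=30,
                   hour_of_day=15.8, day_of_year=210, timezone_offset=8)
rec = MeteoRecord(Ta=20.0, v=0.1, Tmrt=budget.Tmrt, RH=50.0)
print(pet_calc(rec, SubjectProfile()).PET)
```

## CLI

```sh
# synthetic fixture series (deterministic per seed)
biometeo-kit fixture --seed 1 --days 2 --climate temperate --out station.csv

# batch computation; Tmrt simulated from the site/time columns
biometeo-kit compute --input station.csv --indices pet,mpet,utci \
    --simulate-tmrt --out result.csv

# single record
biometeo-kit point --Ta 20 --RH 50 --v 0.1 --Tmrt 20 --index pet
```

Station CSVs use case-insensitive canonical columns (`Ta, RH, VP, v,
height, N, G, Tmrt, lat, lon, elev, doy, hour, tz`, or an ISO-8601
`time` column); wind is reduced from its measurement height (default
10 m) to 1.1 m on read. Invalid rows are skipped with a logged reason.
Subject parameters may be supplied as a TOML file
(`--subject-config subj.toml`) with keys `icl, work, ht, mbody, age,
sex, pos, auto_clo` (`gender` accepted as an alias of `sex`).

## Model notes

- Formula dialects (saturation curve, wind power-law exponent 0.12,
  Kasten-Young air mass, Kasten-Czeplak cloud attenuation, Angstrom
  emissivity, standing-body projected-area factor) are frozen and
  documented in the module docstrings.
- The UTCI polynomial ships as an embedded 210-coefficient table with a
  SHA-256 checksum asserted at import.
- mPET uses a compact 4-segment (head/trunk/arms/legs) core+skin node
  set with a central blood pool, humidity-dependent clothing vapor
  resistance, and clothing insulation adapted to air temperature
  (0.3-2.6 clo, 0.9 clo at 20 degC); its geometry and control constants
  are tabulated in `biometeokit/mpet.py`.
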