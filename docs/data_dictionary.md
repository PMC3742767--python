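# Data dictionary

Column names for every tabular product the package reads or writes.
All coordinates are metres in one local planar frame (x east, y north);
areas are km²; times of day are six-digit numeric `hhmmss`.

## effort.csv — one row per (cruise, transect)

| column | type | meaning |
|---|---|---|
| cruise_id | str | `c<index>_<year>_<month>`, unique per cruise |
| year, month | int | cruise calendar entry |
| end_day | int | last day of the cruise (anchors the 10-day upwelling window) |
| transect_id | str | `T1`..`Tn` |
| vessel | str | Martin / Fulmar / McArthur |
| start_x, start_y, end_x, end_y | float | transect endpoints (m) |
| length_km | float | transect length |

## segments.csv — per-kilometre track records

| column | type | meaning |
|---|---|---|
| cruise_id, transect_id | str | keys into effort |
| seg_index | int | 0-based segment number along the track |
| along_mid_km | float | along-track midpoint of the segment |
| mid_x, mid_y | float | segment midpoint coordinates |
| sea_state | int 0–6 | Beaufort sea state |
| cloud_cover | int 0–9 | cloud cover |
| swell_height_m | float 0–8 | swell height |
| visibility | int 0–9 | observer visibility |
| strip_width_m | float 50–300 | effective strip width |
| time_hhmmss | int | survey time (numeric hhmmss) |
| time_hours | float | same, decimal hours |
| sst, sss, ssf | float | underway surface temperature (°C), salinity (psu), fluorescence (mg/m³); `ssf` empty on cruises without a thermosalinograph |

## sightings.csv — individual sighting records

| column | type | meaning |
|---|---|---|
| sighting_id | str | unique record id |
| cruise_id, transect_id | str | keys |
| along_km | float | along-track position (from the western terminus) |
| species | str | WEGU / COMU / CAAU / RHAU / BRAC |
| count | int | group size |
| behavior | str | foraging, feeding, sitting, flying, ship-attract |
| vessel, strip_width_m, sea_state, cloud_cover, swell_height_m, visibility, time_hhmmss | | survey conditions at the sighting |

Only foraging/feeding/sitting records are retained for modelling.

## ctd.csv — CTD casts

| column | type | meaning |
|---|---|---|
| cruise_id, station_id | str | keys (15–18 stations per cruise) |
| year, month | int | cruise calendar entry |
| x, y | float | station coordinates |
| ssf_1_6m | float | mean fluorescence over the 1–6 m depth layer |
| sst | float | station surface temperature |

## monthly_indices.csv / daily_upwelling.csv

`year, month, npgo, pdo, soi` (monthly climate indices) and
`date, ui` (daily coastal upwelling index).

## model_table.csv — the 3-km binned model table

One row per bin: `bin_id, cruise_id, year, month, end_day, transect_id,
bin_index, along_start_km, along_end_km, length_km (1–3), mid_x, mid_y,
sea_state, cloud_cover, swell_height_m, visibility, strip_width_m,
time_hhmmss, time_hours, sst, sss, ssf, ssf_imputed (bool),
area_km2 (= length x width), count_<SPECIES> per species,
dist_land_m, dist_200_m, dist_sefi_m, npgo, pdo, soi, ui`.

## activities.geojson / region.geojson

Activity footprints carry `name` (one of the six consolidated
activities), `score` (1–5) and `class` (general / dominant / future);
only dominant footprints contribute to the cost layer. The region file
carries `boundary` (polygon), `colony` (point), `mainland` and
`isobath_200m` (lines) plus the cruise calendar.

## cells.csv — prediction cells

`cell_id, cx, cy, in_region, extrapolated (> 25 km from the nearest
surveyed bin), amount_<SPECIES> (standardized habitat, mean 1),
composite, percent_rank (0–1), decile (1–10), human_use_score (0–17)`.

## solutions.csv

`cell_id, scenario (1/2), target (0.1/0.3/0.5), selection_frequency
(fraction of runs selecting the cell), best_selected (bool)`.
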