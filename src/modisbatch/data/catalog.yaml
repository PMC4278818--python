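# Band catalogue for supported MODIS land products.
#
# Stored-unit conventions follow the LP DAAC product tables: valid_range and
# no_data_fill are in the integer units of the delivered subsets; scale_factor
# converts stored integers to physical units.  Quality/reliability bands are
# unscaled rank codes (scale_factor 1) and flagged is_quality_band.
#
# Sinusoidal cell sizes are the exact MODIS grid constants per resolution
# class: 231.656358 m (250 m), 463.312717 m (500 m), 926.625433 m (1 km).

MOD13Q1:
  composite_interval_days: 16
  bands:
    - band_name: 250m_16_days_NDVI
      valid_range: [-2000, 10000]
      no_data_fill: -3000
      scale_factor: 0.0001
      nominal_resolution_m: 250
      actual_cell_size_m: 231.656358
      is_quality_band: false
    - band_name: 250m_16_days_EVI
      valid_range: [-2000, 10000]
      no_data_fill: -3000
      scale_factor: 0.0001
      nominal_resolution_m: 250
      actual_cell_size_m: 231.656358
      is_quality_band: false
    - band_name: 250m_16_days_pixel_reliability
      valid_range: [0, 3]
      no_data_fill: -1
      scale_factor: 1.0
      nominal_resolution_m: 250
      actual_cell_size_m: 231.656358
      is_quality_band: true

# Optional extras beyond the vegetation-index product; constants from the
# LP DAAC product pages.
MOD11A2:
  composite_interval_days: 8
  bands:
    - band_name: LST_Day_1km
      valid_range: [7500, 65535]
      no_data_fill: 0
      scale_factor: 0.02
      nominal_resolution_m: 1000
      actual_cell_size_m: 926.625433
      is_quality_band: false
    - band_name: QC_Day
      valid_range: [0, 254]
      no_data_fill: 255
      scale_factor: 1.0
      nominal_resolution_m: 1000
      actual_cell_size_m: 926.625433
      is_quality_band: true
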