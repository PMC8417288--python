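# Normative OCTA metrics (mean, sd) per plexus for 3 x 3 mm macular scans,
# age 20-67. Device- and population-specific: replace with your own cohort
# for clinical use. Whether the printed spread is SD or SEM is not stated by
# the source; it is used as SD here (configurable by editing this file).
SCP:
  vessel_density_pct: {mean: 48.17, sd: 0.69}
  small_spacing_pct: {mean: 36.97, sd: 0.32}
  large_spacing_pct: {mean: 14.85, sd: 0.46}
  faz_area_mm2: {mean: 0.42, sd: 0.01}
DCP:
  vessel_density_pct: {mean: 53.77, sd: 0.64}
  small_spacing_pct: {mean: 34.03, sd: 0.39}
  large_spacing_pct: {mean: 12.19, sd: 0.33}
  faz_area_mm2: {mean: 0.42, sd: 0.01}
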