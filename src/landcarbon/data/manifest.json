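{
 "table1_accounts": {
  "file": "table1_accounts.csv",
  "source_table": "basic account statistics, 2000-2020",
  "units": {
   "area_km2": "km^2",
   "seq_1e4t": "1e4 t",
   "density_gm2": "g/m^2"
  },
  "flags": {
   "construction_area_only": "no carbon columns are tabulated for construction land",
   "integer_rounding": "sequestration is printed as integer 1e4 t, so densities of small-area classes (lake, wetland) reconstruct only to a few g/m^2"
  }
 },
 "table2_matrix": {
  "file": "table2_matrix.csv",
  "source_table": "average annual land-use transition probabilities, 2000-2020",
  "units": {
   "entries": "probability"
  },
  "flags": {
   "row_sum_deficit": "printed cultivated/forest/grassland/construction rows sum to 1 within 1e-4, but shrub (0.9864), lake (0.9944), ice_snow (0.9979), wasteland (0.9987) and wetland (0.9767) sum to less than 1 as printed"
  }
 },
 "table3_grey_areas": {
  "file": "table3_grey_areas.csv",
  "source_table": "grey-model projected class areas",
  "units": {
   "values": "km^2"
  },
  "flags": {}
 },
 "table4_grey_densities": {
  "file": "table4_grey_densities.csv",
  "source_table": "grey-model projected carbon densities",
  "units": {
   "values": "g/m^2"
  },
  "flags": {}
 },
 "table5_arima_areas": {
  "file": "table5_arima_areas.csv",
  "source_table": "ARIMA projected class areas",
  "units": {
   "values": "km^2"
  },
  "flags": {}
 },
 "table6_arima_densities": {
  "file": "table6_arima_densities.csv",
  "source_table": "ARIMA projected carbon densities",
  "units": {
   "values": "g/m^2"
  },
  "flags": {}
 },
 "table7_areas": {
  "file": "table7_areas.csv",
  "source_table": "ensemble (grey+ARIMA mean) projected areas with stationary overrides",
  "units": {
   "values": "km^2"
  },
  "flags": {
   "mean_override": "lake, ice_snow and wasteland areas are 2000-2020 historical means",
   "unprinted_history": "ice_snow and wasteland 2000-2020 series are shown only as figures in the source, so their means cannot be re-derived from printed data"
  }
 },
 "table8_densities": {
  "file": "table8_densities.csv",
  "source_table": "ensemble projected carbon densities with stationary overrides",
  "units": {
   "values": "g/m^2"
  },
  "flags": {
   "mean_override": "lake and wetland densities are 2000-2020 historical means"
  }
 },
 "table9_impacts": {
  "file": "table9_impacts.csv",
  "source_table": "projected transfer-in/transfer-out impacts, 2025 and 2030",
  "units": {
   "zr_t": "t",
   "zc_t": "t",
   "subtotal_t": "t"
  },
  "printed_totals": {
   "2025": -20753.69,
   "2030": -30837.03
  },
  "flags": {
   "ninth_column_header": "printed header repeats 'Waste land'; stored as wetland",
   "row_sum_mismatch": "printed ZR and ZC row sums differ (17080 vs -37832 for 2025) although the transfer equations as written force them to be equal",
   "subtotal_rounding": "a few printed subtotals differ from ZR+ZC by 1 t (independent rounding of the underlying values)"
  }
 },
 "table10_totals": {
  "file": "table10_totals.csv",
  "source_table": "no-impact standing totals for validation years 2021-2022",
  "units": {
   "values": "1e4 t"
  },
  "flags": {
   "inconsistent_2021_total": "2021 components sum to 12233.554, not the printed 12133.5540; 2022 is internally consistent"
  }
 },
 "table11_impacts": {
  "file": "table11_impacts.csv",
  "source_table": "transfer impacts for validation years 2021-2022",
  "units": {
   "zr_t": "t",
   "zc_t": "t",
   "subtotal_t": "t"
  },
  "printed_totals": {
   "2021": -82226,
   "2022": -45892
  },
  "flags": {
   "ninth_column_header": "printed header repeats 'Wasteland'; stored as wetland",
   "subtotal_rounding": "a few printed subtotals differ from ZR+ZC by 1 t"
  }
 },
 "table12_totals": {
  "file": "table12_totals.csv",
  "source_table": "projected standing stocks and assembled totals, 2025 and 2030",
  "units": {
   "class columns": "1e4 t",
   "impact_t": "t",
   "total": "1e4 t"
  },
  "flags": {
   "lake_wetland_swapped": "printed lake and wetland columns are transposed: 1271.14 km^2 x 149.1 g/m^2 = 18.9527 (the lake stock) prints under wetland; values stored verbatim as printed"
  }
 }
}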