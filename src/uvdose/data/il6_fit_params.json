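{
  "_comment": "Published 4PL fits of IL-6 release against UV set dose, per vessel: lower/upper plateaus in pg/mL, midpoint D_1/2 in mJ/cm^2. Used as calibration inputs for the sigma/rho indices.",
  "3.5cm-dish": {"lower_plateau": 2.0, "slope_factor": 2.4, "midpoint": 18.5, "upper_plateau": 298.9, "r_squared": 0.997},
  "12-well": {"lower_plateau": 26.5, "slope_factor": 9.1, "midpoint": 23.7, "upper_plateau": 314.6, "r_squared": 1.000},
  "24-well": {"lower_plateau": 15.5, "slope_factor": 3.4, "midpoint": 51.4, "upper_plateau": 469.2, "r_squared": 0.998},
  "96-well": {"lower_plateau": 7.3, "slope_factor": 4.2, "midpoint": 166.2, "upper_plateau": 370.9, "r_squared": 0.999}
}
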