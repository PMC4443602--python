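{
  "rat_MAK": {
    "species_strain": "rat (MAK/Brown reference data)",
    "body_weight_kg": 0.25,
    "ventilation_rate_per_kg_m3_day_kg": 0.29,
    "alveolar_surface_area_m2": 0.2972,
    "dead_space_fraction": 0.3333333333333333,
    "macrophage_count_per_kg": 6e7,
    "macrophage_cell_volume_um3": 1166,
    "macrophage_pool_volume_per_kg_ul_kg": 70,
    "clearance_half_time_days": 60,
    "lung_mass_per_kg_g_kg": 4.5,
    "provenance": {
      "body_weight": "West-scaling example rat body weight of 250 g",
      "ventilation_rate_per_kg": "6 h x 60 min/h x 0.8 l/min per (day x kg) = 288 l = 0.29 m^3/(day x kg-rat)",
      "alveolar_surface_area": "Brown et al. value 0.2972 m^2 adopted by MAK (ratio 193 = 57.22/0.2972)",
      "dead_space_fraction": "physiological dead space assumed 1/3 of inhaled volume",
      "macrophage_count_per_kg": "6 x 10^7 alveolar macrophages per kg-rat",
      "macrophage_cell_volume": "rat alveolar macrophage volume 1166 um^3",
      "macrophage_pool_volume_per_kg": "6 x 10^7 x 11.66 x 10^-7 ul/kg-rat = 70 ul/kg-rat",
      "clearance_half_time": "alveolar clearance half-time in rats 60 days (toner and TiO2 alike)",
      "lung_mass_per_kg": "4.5 g lung weight per kg-rat (330-g rat with 1.5 g lung)"
    }
  },
  "rat_reference_1kg": {
    "species_strain": "rat (1 kg reference animal for per-kg volumetric bookkeeping)",
    "body_weight_kg": 1.0,
    "ventilation_rate_per_kg_m3_day_kg": 0.29,
    "alveolar_surface_area_m2": 0.2972,
    "dead_space_fraction": 0.3333333333333333,
    "macrophage_count_per_kg": 6e7,
    "macrophage_cell_volume_um3": 1166,
    "macrophage_pool_volume_per_kg_ul_kg": 70,
    "clearance_half_time_days": 60,
    "lung_mass_per_kg_g_kg": 4.5,
    "provenance": {
      "body_weight": "reference body weight 1 kg-rat used by the volumetric sensitivity grid",
      "ventilation_rate_per_kg": "0.29 m^3/kg-rat and day (encodes the 6-h daily exposure window)",
      "alveolar_surface_area": "as rat_MAK",
      "dead_space_fraction": "1/3 of inhaled volume",
      "macrophage_count_per_kg": "6 x 10^7 per kg-rat",
      "macrophage_cell_volume": "1166 um^3",
      "macrophage_pool_volume_per_kg": "7 x 10^10 um^3/kg-rat = 70 ul/kg-rat",
      "clearance_half_time": "60 days",
      "lung_mass_per_kg": "4.5 g/kg-rat"
    }
  },
  "rat_F344_Stone": {
    "species_strain": "rat F344 (Stone et al., stereological reference method)",
    "body_weight_kg": 0.29,
    "ventilation_rate_per_kg_m3_day_kg": 0.29,
    "alveolar_surface_area_m2": 0.41,
    "dead_space_fraction": 0.3333333333333333,
    "macrophage_count_per_kg": null,
    "macrophage_cell_volume_um3": null,
    "macrophage_pool_volume_per_kg_ul_kg": 70,
    "clearance_half_time_days": 60,
    "lung_mass_per_kg_g_kg": 4.5,
    "provenance": {
      "body_weight": "F344 rats of 290 g in the Stone et al. morphometry",
      "ventilation_rate_per_kg": "as rat_MAK",
      "alveolar_surface_area": "0.41 m^2 +/- 0.04, in-situ instillation, electron microscopy (ATS/ERS reference method)",
      "dead_space_fraction": "1/3 of inhaled volume",
      "macrophage_pool_volume_per_kg": "as rat_MAK",
      "clearance_half_time": "60 days",
      "lung_mass_per_kg": "4.5 g/kg-rat"
    }
  },
  "rat_Yeh_330g": {
    "species_strain": "rat Long-Evans (Yeh cast study, 330 g)",
    "body_weight_kg": 0.33,
    "ventilation_rate_per_kg_m3_day_kg": 0.29,
    "alveolar_surface_area_m2": 0.5725,
    "dead_space_fraction": 0.3333333333333333,
    "macrophage_count_per_kg": null,
    "macrophage_cell_volume_um3": null,
    "macrophage_pool_volume_per_kg_ul_kg": 70,
    "clearance_half_time_days": 60,
    "lung_mass_per_kg_g_kg": 4.5,
    "provenance": {
      "body_weight": "single 330-g Long-Evans rat",
      "ventilation_rate_per_kg": "as rat_MAK",
      "alveolar_surface_area": "0.5725 m^2, silicone rubber cast with mathematical extrapolation",
      "dead_space_fraction": "1/3 of inhaled volume",
      "macrophage_pool_volume_per_kg": "as rat_MAK",
      "clearance_half_time": "60 days",
      "lung_mass_per_kg": "4.5 g/kg-rat"
    }
  },
  "human_MAK_Brown": {
    "species_strain": "human (MAK/Brown reference data, 400-day clearance)",
    "body_weight_kg": 70,
    "ventilation_rate_per_kg_m3_day_kg": 0.14285714285714285,
    "alveolar_surface_area_m2": 57.22,
    "dead_space_fraction": 0.3333333333333333,
    "macrophage_count_per_kg": null,
    "macrophage_cell_volume_um3": null,
    "macrophage_pool_volume_per_kg_ul_kg": 500,
    "clearance_half_time_days": 400,
    "lung_mass_per_kg_g_kg": null,
    "provenance": {
      "body_weight": "reference worker body weight 70 kg",
      "ventilation_rate_per_kg": "10 m^3 per 70 kg-human and day (one working shift)",
      "alveolar_surface_area": "Brown et al. value 57.22 m^2 adopted by MAK",
      "dead_space_fraction": "1/3 of inhaled volume",
      "macrophage_pool_volume_per_kg": "50 x 10^10 um^3/kg-human = 500 ul/kg-human",
      "clearance_half_time": "alveolar clearance half-time in humans of 400 days as applied by MAK"
    }
  },
  "human_Gehr": {
    "species_strain": "human (Gehr et al. stereology, 400-day clearance)",
    "body_weight_kg": 70,
    "ventilation_rate_per_kg_m3_day_kg": 0.14285714285714285,
    "alveolar_surface_area_m2": 143,
    "dead_space_fraction": 0.3333333333333333,
    "macrophage_count_per_kg": null,
    "macrophage_cell_volume_um3": null,
    "macrophage_pool_volume_per_kg_ul_kg": 500,
    "clearance_half_time_days": 400,
    "lung_mass_per_kg_g_kg": null,
    "provenance": {
      "body_weight": "reference worker body weight 70 kg",
      "ventilation_rate_per_kg": "10 m^3 per 70 kg-human and day",
      "alveolar_surface_area": "143 m^2 +/- 12, in-situ instillation on 8 humans (ATS/ERS reference method)",
      "dead_space_fraction": "1/3 of inhaled volume",
      "macrophage_pool_volume_per_kg": "500 ul/kg-human",
      "clearance_half_time": "400 days (MAK assumption, retained for comparability)"
    }
  },
  "human_Gregoratto": {
    "species_strain": "human (Gehr surface, Gregoratto 255-day alveolar-interstitial clearance)",
    "body_weight_kg": 70,
    "ventilation_rate_per_kg_m3_day_kg": 0.14285714285714285,
    "alveolar_surface_area_m2": 143,
    "dead_space_fraction": 0.3333333333333333,
    "macrophage_count_per_kg": null,
    "macrophage_cell_volume_um3": null,
    "macrophage_pool_volume_per_kg_ul_kg": 500,
    "clearance_half_time_days": 255,
    "lung_mass_per_kg_g_kg": null,
    "provenance": {
      "body_weight": "reference worker body weight 70 kg",
      "ventilation_rate_per_kg": "10 m^3 per 70 kg-human and day",
      "alveolar_surface_area": "143 m^2 (Gehr et al.)",
      "dead_space_fraction": "1/3 of inhaled volume",
      "macrophage_pool_volume_per_kg": "500 ul/kg-human",
      "clearance_half_time": "255 days, two-compartment alveolar-interstitial model fit (Gregoratto et al.); sensitivity grid rounds to 250 days"
    }
  }
}
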