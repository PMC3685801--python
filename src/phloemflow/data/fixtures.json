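{
  "schema_version": 1,
  "fixtures": {
    "wheat_grain_table3": {
      "description": "Constants behind the wheat-grain plasmodesma feasibility grid",
      "values": {
        "volume_import_rate": {"value": 10.0, "units": "uL day^-1", "citation": "phloem import into a developing wheat grain (Fisher)"},
        "observed_pd_count": {"value": 44000000.0, "units": "plasmodesmata per grain", "citation": "SE/CC - vascular parenchyma interface counts (Wang et al.)"},
        "pressure_differential": {"value": 1.0, "units": "MPa", "citation": "SE minus vascular parenchyma turgor, normally watered grain (Fisher & Cash-Clark)"},
        "sap_viscosity": {"value": 2e-09, "units": "MPa s", "citation": "averaged phloem sap viscosity (Mullendore et al.)"},
        "wall_thickness": {"value": 500.0, "units": "nm", "citation": "plasmodesma length, SE/CC to vascular parenchyma wall (Fisher & Cash-Clark)"},
        "sleeve_circle_radius": {"value": 10.5, "units": "nm", "citation": "half the 21 nm internal plasmodesma radius (Wang et al.)"},
        "occupancy_fraction": {"value": 0.5, "units": "dimensionless", "citation": "microchannel diameters occupy 50% of the sleeve circumference (Fisher & Cash-Clark packing rule)"},
        "sucrose_diffusivity": {"value": 520000000.0, "units": "nm^2 s^-1", "citation": "sucrose in water at 25 degC"}
      }
    },
    "wheat_grain_normal": {
      "description": "Turgor pair, normally watered developing wheat grain",
      "values": {
        "se_pressure": {"value": 1.11, "units": "MPa", "citation": "aphid stylet micromanometry (Fisher & Cash-Clark)"},
        "sink_cell_pressure": {"value": 0.12, "units": "MPa", "citation": "vascular parenchyma pressure probe (Fisher & Cash-Clark)"},
        "printed_differential": {"value": 1.0, "units": "MPa", "citation": "as tabulated (Fisher & Cash-Clark)"}
      }
    },
    "wheat_grain_water_stressed": {
      "description": "Turgor pair, water-stressed developing wheat grain",
      "values": {
        "se_pressure": {"value": 1.3, "units": "MPa", "citation": "aphid stylet micromanometry (Fisher & Cash-Clark)"},
        "sink_cell_pressure": {"value": 0.08, "units": "MPa", "citation": "vascular parenchyma pressure probe (Fisher & Cash-Clark)"},
        "printed_differential": {"value": 1.12, "units": "MPa", "citation": "as tabulated (Fisher & Cash-Clark)"}
      }
    },
    "barley_root_high_k": {
      "description": "Turgor pair, barley root tip, potassium-replete plants",
      "values": {
        "se_pressure": {"value": 1.62, "units": "MPa", "citation": "aphid stylet micromanometry (Gould et al.)"},
        "sink_cell_pressure": {"value": 0.33, "units": "MPa", "citation": "elongating epidermal/cortical cell pressure probe (Gould et al.)"},
        "printed_differential": {"value": 1.29, "units": "MPa", "citation": "as tabulated (Gould et al.)"}
      }
    },
    "barley_root_low_k": {
      "description": "Turgor pair, barley root tip, potassium-deficient plants",
      "values": {
        "se_pressure": {"value": 1.32, "units": "MPa", "citation": "aphid stylet micromanometry (Gould et al.)"},
        "sink_cell_pressure": {"value": 0.32, "units": "MPa", "citation": "elongating epidermal/cortical cell pressure probe (Gould et al.)"},
        "printed_differential": {"value": 1.0, "units": "MPa", "citation": "as tabulated (Gould et al.)"}
      }
    },
    "maize_root_osmotic": {
      "description": "Osmotic-potential pair, maize root tip",
      "values": {
        "se_osmotic_potential": {"value": -1.62, "units": "MPa", "citation": "sieve element sap osmometry (Warmbrodt)"},
        "cortical_osmotic_potential": {"value": -0.98, "units": "MPa", "citation": "elongating cortical cell osmometry (Warmbrodt)"},
        "printed_difference": {"value": -0.64, "units": "MPa", "citation": "as tabulated (Warmbrodt)"}
      }
    },
    "barley_root_osmotic": {
      "description": "Osmotic-potential pair, barley root tip",
      "values": {
        "se_osmotic_potential": {"value": -1.42, "units": "MPa", "citation": "sieve element sap osmometry (Pritchard)"},
        "cortical_osmotic_potential": {"value": -0.71, "units": "MPa", "citation": "elongating cortical cell osmometry (Pritchard)"},
        "printed_difference": {"value": -0.71, "units": "MPa", "citation": "as tabulated (Pritchard)"}
      }
    },
    "ricinus_fruit_excision": {
      "description": "Castor-bean fruit excision experiment on the pedicel sieve tubes",
      "values": {
        "se_pressure": {"value": 1.0, "units": "MPa", "citation": "Ricinus ST pressure from osmotic and water potentials (Smith & Milburn)"},
        "sink_turgor_low": {"value": 0.1, "units": "MPa", "citation": "fruit sink cell turgor, low end (Saladie et al.; Wada et al.)"},
        "sink_turgor_high": {"value": 0.2, "units": "MPa", "citation": "fruit sink cell turgor, high end (Saladie et al.; Wada et al.)"},
        "observed_flux_fold": {"value": 19.0, "units": "fold", "citation": "sucrose flux increase through the pedicel stump on fruit excision (Kallarackal & Milburn)"},
        "published_residual_fold_high": {"value": 17.8, "units": "fold", "citation": "published residual attributed to removed unloading resistance, 0.1 MPa turgor case"},
        "published_residual_fold_low": {"value": 14.2, "units": "fold", "citation": "published residual attributed to removed unloading resistance, 0.2 MPa turgor case"}
      }
    },
    "sieve_tube_pressures": {
      "description": "Directly measured sieve-tube hydrostatic pressures by organ",
      "values": {
        "barley_leaf": {"range": [0.8, 1.4], "units": "MPa", "citation": "aphid stylet micromanometry (Gould et al.)"},
        "barley_root": {"mean": 1.62, "sd": 0.05, "units": "MPa", "citation": "aphid stylet micromanometry (Gould et al.)"},
        "sow_thistle_leaf": {"range": [1.0, 1.5], "units": "MPa", "citation": "aphid stylet micromanometry (Gould et al.)"},
        "sow_thistle_stem": {"range": [0.7, 1.0], "units": "MPa", "citation": "aphid stylet micromanometry (Gould et al.)"},
        "wheat_peduncle": {"mean": 2.35, "sd": 0.56, "units": "MPa", "citation": "aphid stylet micromanometry (Fisher & Cash-Clark)"},
        "wheat_grain": {"mean": 1.16, "sd": 0.26, "units": "MPa", "citation": "aphid stylet micromanometry (Fisher & Cash-Clark)"},
        "willow_leaf": {"range": [0.51, 0.93], "units": "MPa", "citation": "aphid stylet micromanometry (Wright & Fisher)"},
        "willow_bark_strip": {"range": [0.47, 1.2], "units": "MPa", "citation": "aphid stylet micromanometry (Wright & Fisher)"}
      }
    },
    "sucrose_concentrations": {
      "description": "Sucrose concentration ranges either side of the wheat-grain unloading interface",
      "values": {
        "sieve_element": {"range": [450.0, 600.0], "units": "mM", "citation": "SE sap from exuding pedicels (Fisher & Gifford)"},
        "vascular_parenchyma": {"range": [200.0, 260.0], "units": "mM", "citation": "frozen tissue slices containing vascular parenchyma (Fisher & Wang)"}
      }
    },
    "microchannel_radii": {
      "description": "Plasmodesmal microchannel radius estimates from tracer Stokes radii",
      "values": {
        "phloem_domain": {"range": [4.0, 8.0], "units": "nm", "citation": "fluorochrome mobility, phloem symplasmic domains"},
        "non_phloem_domain": {"range": [1.0, 2.0], "units": "nm", "citation": "fluorochrome mobility, non-phloem symplasmic domains"}
      }
    }
  }
}
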