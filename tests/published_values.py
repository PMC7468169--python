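"""Printed reference values from the published budget sheets for the three
Korean case-study farms, frozen for comparison tests.

All values kg/yr (percent where noted), printed at one decimal (two in the
scenario P sheet).  Terms the sheets leave blank ("-") are omitted.
"""

# farm -> approach -> {"inputs": {...}, "outputs": {...},
#                      "total_inputs", "total_outputs", "surplus"[, agns, hgns]}
NITROGEN_BUDGETS = {
    "farm1": {
        "current_gnb": {
            "inputs": {"chemical_fertilizer": 8.0, "livestock_manure": 11075.9,
                       "biological_n_fixation": 9.9, "atmospheric_deposition": 15.9,
                       "planting_materials": 0.3},
            "outputs": {"crop_harvesting": 26.4},
            "total_inputs": 11110.0, "total_outputs": 26.4, "surplus": 11083.6,
        },
        "ideal_gnb": {
            "inputs": {"chemical_fertilizer": 8.0, "livestock_manure": 11075.9,
                       "biological_n_fixation": 9.9, "atmospheric_deposition": 15.9,
                       "planting_materials": 0.3},
            "outputs": {"crop_harvesting": 26.4, "soil_stock_change": 40.9},
            "total_inputs": 11110.0, "total_outputs": 67.3, "surplus": 11042.7,
            "agns": 6044.8, "hgns": 4997.9,
        },
        "ssb": {
            "inputs": {"chemical_fertilizer": 8.0, "liquid_compost": 5031.1,
                       "biological_n_fixation": 9.9, "atmospheric_deposition": 15.9,
                       "planting_materials": 0.3},
            "outputs": {"crop_harvesting": 26.4, "denitrification_fertilizer": 1.2,
                        "denitrification_compost": 654.0, "denitrification_arable_land": 2.0,
                        "volatilization_fertilizer": 1.1, "volatilization_compost": 1157.2,
                        "leaching": 1342.3, "runoff": 759.8},
            "total_inputs": 5065.2, "total_outputs": 3943.9, "surplus": 1121.2,
        },
    },
    "farm2": {
        "current_gnb": {
            "inputs": {"livestock_manure": 28480.9, "biological_n_fixation": 49.5,
                       "atmospheric_deposition": 79.5, "planting_materials": 7.9},
            "outputs": {"crop_harvesting": 88.6},
            "total_inputs": 28617.9, "total_outputs": 88.6, "surplus": 28529.2,
        },
        "ideal_gnb": {
            "inputs": {"livestock_manure": 28480.9, "biological_n_fixation": 49.5,
                       "atmospheric_deposition": 79.5, "planting_materials": 7.9},
            "outputs": {"crop_harvesting": 88.6, "soil_stock_change": 57.5},
            "total_inputs": 28617.9, "total_outputs": 146.1, "surplus": 28471.7,
            "agns": 14284.5, "hgns": 14187.2,
        },
        "ssb": {
            "inputs": {"liquid_compost": 12832.6, "solid_compost": 1363.8,
                       "biological_n_fixation": 49.5, "atmospheric_deposition": 79.5,
                       "planting_materials": 7.9},
            "outputs": {"crop_harvesting": 88.6, "denitrification_fertilizer": 0.0,
                        "denitrification_compost": 1845.5, "denitrification_arable_land": 9.9,
                        "volatilization_fertilizer": 0.0, "volatilization_compost": 3265.2,
                        "leaching": 3798.3, "runoff": 2150.0},
            "total_inputs": 14333.4, "total_outputs": 11157.6, "surplus": 3175.8,
        },
    },
    "farm3": {
        "current_gnb": {
            "inputs": {"chemical_fertilizer": 16.0, "livestock_manure": 23734.1,
                       "biological_n_fixation": 34.8, "atmospheric_deposition": 55.9,
                       "planting_materials": 4.6},
            "outputs": {"crop_harvesting": 68.4},
            "total_inputs": 23845.4, "total_outputs": 68.4, "surplus": 23777.1,
        },
        "ideal_gnb": {
            "inputs": {"chemical_fertilizer": 16.0, "livestock_manure": 23734.1,
                       "biological_n_fixation": 34.8, "atmospheric_deposition": 55.9,
                       "planting_materials": 4.6},
            "outputs": {"crop_harvesting": 68.4, "soil_stock_change": -46.5},
            "total_inputs": 23845.4, "total_outputs": 21.9, "surplus": 23823.6,
            "agns": 16372.0, "hgns": 7451.6,
        },
        "ssb": {
            "inputs": {"chemical_fertilizer": 16.0, "liquid_compost": 5551.2,
                       "solid_compost": 1810.9, "biological_n_fixation": 34.8,
                       "atmospheric_deposition": 55.9, "planting_materials": 4.6},
            "outputs": {"crop_harvesting": 68.4, "denitrification_fertilizer": 2.4,
                        "denitrification_compost": 957.1, "denitrification_arable_land": 7.0,
                        "volatilization_fertilizer": 2.2, "volatilization_compost": 1693.3,
                        "leaching": 1980.5, "runoff": 1121.0},
            "total_inputs": 7473.4, "total_outputs": 5831.8, "surplus": 1641.6,
        },
    },
}

PHOSPHORUS_BUDGETS = {
    "farm1": {
        "current_gnb": {
            "inputs": {"chemical_fertilizer": 8.0, "livestock_manure": 1954.6,
                       "atmospheric_deposition": 0.4, "planting_materials": 0.5},
            "outputs": {"crop_harvesting": 5.9},
            "total_inputs": 1963.5, "total_outputs": 5.9, "surplus": 1957.6,
        },
        "ideal_gnb": {
            "inputs": {"chemical_fertilizer": 8.0, "livestock_manure": 1954.6,
                       "atmospheric_deposition": 0.4, "planting_materials": 0.5},
            "outputs": {"crop_harvesting": 5.9, "soil_stock_change": -40.8},
            "total_inputs": 1963.5, "total_outputs": -34.9, "surplus": 1998.4,
        },
        "ssb": {
            "inputs": {"chemical_fertilizer": 8.0, "liquid_compost": 72.6,
                       "atmospheric_deposition": 0.4, "planting_materials": 0.5},
            "outputs": {"crop_harvesting": 5.9, "leaching": 28.8, "runoff": 6.0},
            "total_inputs": 81.5, "total_outputs": 40.7, "surplus": 40.8,
        },
    },
    "farm2": {
        "current_gnb": {
            "inputs": {"livestock_manure": 5026.1, "atmospheric_deposition": 1.9,
                       "planting_materials": 3.0},
            "outputs": {"crop_harvesting": 19.2},
            "total_inputs": 5031.0, "total_outputs": 19.2, "surplus": 5011.8,
        },
        "ideal_gnb": {
            "inputs": {"livestock_manure": 5026.1, "atmospheric_deposition": 1.9,
                       "planting_materials": 3.0},
            "outputs": {"crop_harvesting": 19.2, "soil_stock_change": -46.5},
            "total_inputs": 5031.0, "total_outputs": -27.3, "surplus": 5058.3,
        },
        "ssb": {
            "inputs": {"liquid_compost": 185.1, "solid_compost": 1022.9,
                       "atmospheric_deposition": 1.9, "planting_materials": 3.0},
            "outputs": {"crop_harvesting": 19.2, "leaching": 428.2, "runoff": 89.8},
            "total_inputs": 1212.9, "total_outputs": 537.1, "surplus": 675.8,
        },
    },
    "farm3": {
        "current_gnb": {
            "inputs": {"chemical_fertilizer": 16.0, "livestock_manure": 4188.4,
                       "atmospheric_deposition": 1.4, "planting_materials": 2.0},
            "outputs": {"crop_harvesting": 14.9},
            "total_inputs": 4207.8, "total_outputs": 14.9, "surplus": 4192.8,
        },
        "ideal_gnb": {
            "inputs": {"chemical_fertilizer": 16.0, "livestock_manure": 4188.4,
                       "atmospheric_deposition": 1.4, "planting_materials": 2.0},
            "outputs": {"crop_harvesting": 14.9, "soil_stock_change": 204.4},
            "total_inputs": 4207.8, "total_outputs": 219.3, "surplus": 3988.4,
        },
        "ssb": {
            "inputs": {"chemical_fertilizer": 16.0, "liquid_compost": 85.4,
                       "solid_compost": 925.2, "atmospheric_deposition": 1.4,
                       "planting_materials": 2.0},
            "outputs": {"crop_harvesting": 14.9, "leaching": 363.6, "runoff": 76.2},
            "total_inputs": 1030.0, "total_outputs": 454.7, "surplus": 575.2,
        },
    },
}

# (farm, phase, method) -> (N loading, P loading) kg/yr; 13 published rows
LOADING_COMPARISON = {
    ("farm1", "liquid", "intermittent_aeration"): (5031.1, 72.6),
    ("farm1", "liquid", "continuous_aeration"): (2515.6, 38.7),
    ("farm1", "liquid", "storage_only"): (6482.4, 440.2),
    ("farm2", "solid", "turning_aeration"): (1363.8, 1022.9),
    ("farm2", "solid", "turning"): (1960.7, 1001.7),
    ("farm2", "liquid", "intermittent_aeration"): (12832.6, 185.1),
    ("farm2", "liquid", "continuous_aeration"): (6416.2, 98.7),
    ("farm2", "liquid", "storage_only"): (16533.9, 1122.8),
    ("farm3", "solid", "turning_aeration"): (1259.8, 944.8),
    ("farm3", "solid", "turning"): (1810.9, 925.2),
    ("farm3", "liquid", "intermittent_aeration"): (11102.5, 160.1),
    ("farm3", "liquid", "continuous_aeration"): (5551.2, 85.4),
    ("farm3", "liquid", "storage_only"): (14305.1, 971.5),
}

# suggested-treatment soil-system budgets (continuous aeration liquid,
# turning+aeration solid): farm -> (total inputs, total outputs, surplus)
SCENARIO_N = {
    "farm1": (2549.43, 1994.3, 555.1),
    "farm2": (7909.99, 6181.9, 1728.0),
    "farm3": (6918.28, 5403.9, 1514.3),
}
SCENARIO_P = {
    "farm1": (47.6, 26.21, 21.38),
    "farm2": (1126.6, 499.94, 626.70),
    "farm3": (1049.6, 462.77, 586.84),
}

# published surplus reductions under the suggested methods, percent
SCENARIO_REDUCTION_N = {"farm1": 49.4, "farm2": 44.6, "farm3": 7.4}
SCENARIO_REDUCTION_P = {"farm1": 47.6, "farm2": 7.3, "farm3": -1.9}
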