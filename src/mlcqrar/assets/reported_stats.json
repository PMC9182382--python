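{
  "log_km~log_KAM": {
    "response": "log_km",
    "predictors": ["log_KAM"],
    "coefficients": ["0.585", "0.932"],
    "standard_errors": ["0.102", "0.044"],
    "n": 15,
    "R": "0.9861",
    "R_adj": "0.9849",
    "sd": "0.1612",
    "F": "456",
    "PRESS": null,
    "MSE": null,
    "vif_max": null
  },
  "log_Kp~log_km": {
    "response": "log_Kp",
    "predictors": ["log_km", "HBD", "HBA", "NRB"],
    "coefficients": ["-5.329", "0.597", "-0.669", "-0.345", "0.197"],
    "standard_errors": ["0.156", "0.041", "0.075", "0.061", "0.044"],
    "n": 15,
    "R": "0.9893",
    "R_adj": "0.9850",
    "sd": "0.110",
    "F": "116",
    "PRESS": "0.276",
    "MSE": "0.012",
    "vif_max": "3.6"
  },
  "log_Kp~log_KAM": {
    "response": "log_Kp",
    "predictors": ["log_KAM", "HBD", "HBA", "NRB"],
    "coefficients": ["-4.900", "0.552", "-0.714", "-0.378", "0.213"],
    "standard_errors": ["0.218", "0.060", "0.118", "0.092", "0.067"],
    "n": 15,
    "R": "0.9747",
    "R_adj": "0.9644",
    "sd": "0.169",
    "F": "48",
    "PRESS": "0.610",
    "MSE": "0.0286",
    "vif_max": "3.5"
  },
  "log_Kwcell~log_km": {
    "response": "log_Kwcell",
    "predictors": ["log_km", "HBD", "HBA", "NRB"],
    "coefficients": ["-2.773", "0.062", "-1.846", "-0.368", "0.076"],
    "standard_errors": ["0.295", "0.078", "0.143", "0.115", "0.083"],
    "n": 15,
    "R": "0.9740",
    "R_adj": "0.9634",
    "sd": "0.209",
    "F": "47",
    "PRESS": "4.064",
    "MSE": "0.0435",
    "vif_max": "3.6"
  },
  "log_Kwcell~log_KAM": {
    "response": "log_Kwcell",
    "predictors": ["log_KAM", "HBD", "HBA", "NRB"],
    "coefficients": ["-2.762", "0.079", "-1.867", "-0.356", "0.064"],
    "standard_errors": ["0.262", "0.073", "0.142", "0.111", "0.081"],
    "n": 15,
    "R": "0.9753",
    "R_adj": "0.9652",
    "sd": "0.203",
    "F": "49",
    "PRESS": "4.889",
    "MSE": "0.0414",
    "vif_max": "3.5"
  },
  "log_KHSA~log_km": {
    "response": "log_KHSA",
    "predictors": ["log_km", "HBD", "HBA", "NRB"],
    "coefficients": ["4.619", "0.251", "0.106", "-0.381", "0.150"],
    "standard_errors": ["0.350", "0.093", "0.170", "0.136", "0.100"],
    "n": 15,
    "R": "0.8953",
    "R_adj": "0.8498",
    "sd": "0.248",
    "F": "11",
    "PRESS": "1.078",
    "MSE": "0.0615",
    "vif_max": "3.6"
  },
  "log_KHSA~log_KAM": {
    "response": "log_KHSA",
    "predictors": ["log_KAM", "HBD", "HBA", "NRB"],
    "coefficients": ["4.843", "0.204", "0.109", "-0.415", "0.175"],
    "standard_errors": ["0.351", "0.097", "0.190", "0.148", "0.108"],
    "n": 15,
    "R": "0.8722",
    "R_adj": "0.8155",
    "sd": "0.272",
    "F": "8",
    "PRESS": "1.326",
    "MSE": "0.0741",
    "vif_max": "3.5"
  },
  "log_BB~log_km": {
    "response": "log_BB",
    "predictors": ["log_km", "HBD", "HBA", "NRB"],
    "coefficients": ["-0.375", "0.254", "-0.454", "0.041", "-0.006"],
    "standard_errors": ["0.078", "0.021", "0.038", "0.030", "0.023"],
    "n": 15,
    "R": "0.9836",
    "R_adj": "0.9770",
    "sd": "0.055",
    "F": "75",
    "PRESS": "0.090",
    "MSE": "0.0031",
    "vif_max": "3.6"
  },
  "log_BB~log_KAM": {
    "response": "log_BB",
    "predictors": ["log_KAM", "HBD", "HBA", "NRB"],
    "coefficients": ["-0.205", "0.242", "-0.479", "0.032", "-0.003"],
    "standard_errors": ["0.073", "0.020", "0.039", "0.031", "0.022"],
    "n": 15,
    "R": "0.9831",
    "R_adj": "0.9762",
    "sd": "0.056",
    "F": "72",
    "PRESS": "0.069",
    "MSE": "0.0032",
    "vif_max": "3.5"
  },
  "LD50~log_km": {
    "response": "LD50",
    "predictors": ["log_km", "HBD", "HBA", "NRB"],
    "coefficients": ["2870", "-253", "650", "-194", "-245"],
    "standard_errors": ["411", "109", "199", "160", "116"],
    "n": 15,
    "R": "0.9330",
    "R_adj": "0.9048",
    "sd": "291",
    "F": "17",
    "PRESS": "2078292",
    "MSE": "84613",
    "vif_max": "3.6"
  },
  "LD50~log_KAM": {
    "response": "LD50",
    "predictors": ["log_KAM", "HBD", "HBA", "NRB"],
    "coefficients": ["2714", "-251", "682", "-192", "-242"],
    "standard_errors": ["367", "102", "192", "155", "113"],
    "n": 15,
    "R": "0.9358",
    "R_adj": "0.9088",
    "sd": "285",
    "F": "18",
    "PRESS": "2017628",
    "MSE": "81170",
    "vif_max": "3.5"
  }
}
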