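{
  "_comment": "Surface-class profiles for the synthetic field-campaign generator. Fields listed under 'assumed' were not printed in the source study and carry plausible values chosen for simulation only; all other values are the printed ones. Fluxes in ug N m-2 day-1, mineral N in mg N kg-1 DW, WFPS as a fraction.",
  "vegetated_holocene": {
    "wfps_range": [0.06, 0.15],
    "no3_range": [0.1, 2.0],
    "nh4_range": [0.5, 5.0],
    "cn_ratio": 38.0,
    "flux_median": -4.0,
    "flux_range": [-19.0, 10.0],
    "assumed": ["no3_range", "nh4_range", "flux_range"]
  },
  "bare_fresh_yedoma": {
    "wfps_range": [0.67, 1.0],
    "no3_range": [0.1, 5.0],
    "nh4_range": [20.0, 50.0],
    "cn_ratio": 14.5,
    "flux_median": 10.0,
    "flux_range": [-19.0, 63.0],
    "assumed": ["no3_range", "nh4_range", "flux_median", "flux_range", "cn_ratio_midpoint_of_14_15"]
  },
  "bare_earlier_yedoma": {
    "wfps_range": [0.45, 0.85],
    "no3_range": [0.5, 10.0],
    "nh4_range": [5.0, 30.0],
    "cn_ratio": 14.5,
    "flux_median": 30.0,
    "flux_range": [5.0, 200.0],
    "assumed": ["wfps_range", "no3_range", "nh4_range", "flux_median", "flux_range"]
  },
  "yedoma_moss": {
    "wfps_range": [0.42, 0.84],
    "no3_range": [1.0, 20.0],
    "nh4_range": [2.0, 20.0],
    "cn_ratio": 14.5,
    "flux_median": 314.0,
    "flux_range": [26.0, 3090.0],
    "assumed": ["no3_range", "nh4_range"]
  },
  "yedoma_grass": {
    "wfps_range": [0.42, 0.84],
    "no3_range": [1.0, 30.0],
    "nh4_range": [2.0, 20.0],
    "cn_ratio": 14.5,
    "flux_median": 548.0,
    "flux_range": [133.0, 6286.0],
    "assumed": ["no3_range", "nh4_range"]
  },
  "bare_sand": {
    "wfps_range": [0.2, 0.6],
    "no3_range": [0.05, 1.0],
    "nh4_range": [0.1, 2.0],
    "cn_ratio": 10.0,
    "flux_median": 2.0,
    "flux_range": [0.5, 10.0],
    "assumed": ["wfps_range", "no3_range", "nh4_range", "cn_ratio", "flux_median", "flux_range"]
  }
}
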