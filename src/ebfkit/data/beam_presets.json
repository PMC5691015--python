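{
  "6": {
    "nominal_mev": 6.0,
    "r50_mm": 23.5,
    "rp_mm": 30.0,
    "dmax_mm": 13.0,
    "surface_fraction": 0.85,
    "tail_percent": 1.5,
    "grid_max_mm": 55.0,
    "schedule_mm": {"start": 3, "stop": 29, "step": 1}
  },
  "9": {
    "nominal_mev": 9.0,
    "r50_mm": 36.0,
    "rp_mm": 45.5,
    "dmax_mm": 20.0,
    "surface_fraction": 0.85,
    "tail_percent": 1.5,
    "grid_max_mm": 78.0,
    "schedule_mm": {"start": 3, "stop": 45, "step": 2}
  },
  "12": {
    "nominal_mev": 12.0,
    "r50_mm": 48.5,
    "rp_mm": 60.5,
    "dmax_mm": 27.0,
    "surface_fraction": 0.85,
    "tail_percent": 1.5,
    "grid_max_mm": 98.0,
    "schedule_mm": {"start": 3, "stop": 60, "step": 3}
  },
  "15": {
    "nominal_mev": 15.0,
    "r50_mm": 63.0,
    "rp_mm": 78.0,
    "dmax_mm": 33.0,
    "surface_fraction": 0.85,
    "tail_percent": 1.5,
    "grid_max_mm": 122.0,
    "schedule_mm": {"start": 4, "stop": 76, "step": 4}
  }
}
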