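{
  "type": "object",
  "required": ["seed", "device", "groups"],
  "properties": {
    "seed": {"type": "integer"},
    "versions": {"type": "object"},
    "device": {
      "type": "object",
      "required": ["midpoint_B_mT", "calibration_target_mT"],
      "properties": {
        "midpoint_B_mT": {"type": "number"},
        "calibration_target_mT": {"type": "number"},
        "mean_grad_B_T_per_m": {"type": "number"}
      }
    },
    "simulation": {
      "type": "object",
      "required": ["median_angle_deg", "mode_bin_deg", "n_particles", "n_excluded"],
      "properties": {
        "median_angle_deg": {"type": "number"},
        "mode_bin_deg": {"type": "array", "items": {"type": "number"}},
        "n_particles": {"type": "integer"},
        "n_excluded": {"type": "integer"}
      }
    },
    "groups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "n_images"],
        "properties": {
          "name": {"type": "string"},
          "n_images": {"type": "integer"},
          "fitted_peak_deg": {"type": "number"},
          "fitted_sd_deg": {"type": "number"},
          "is_anisotropic": {"type": "boolean"},
          "mean_gap_count": {"type": "number"},
          "sd_gap_count": {"type": "number"}
        }
      }
    }
  }
}
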