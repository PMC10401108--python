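{
  "phantom": {
    "volume_shape": [128, 128, 128],
    "voxel_size": 0.04,
    "n_cells": 1,
    "vesicle_density": 0.5,
    "vesicle_volume_law": {"family": "lognormal", "mean": 0.08, "sigma_log": 0.4},
    "granule_diameter": 0.08,
    "nanochannel_diameter": 0.08,
    "cell_radius": 1.6,
    "filling_factor_sd": 0.0,
    "frac_empty_vesicles": 0.3,
    "noise_sd": 5.0,
    "seed": 1
  },
  "logistics": {
    "lacunar_density": 196000,
    "precursor_per_vesicle": 0.058,
    "mineralization_duration": 1440,
    "vesicles_per_cell": 37,
    "travel_distance": 10
  }
}
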