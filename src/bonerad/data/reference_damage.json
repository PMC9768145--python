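{
  "description": "Published comparison values for X-ray radiation damage in pike cleithrum bone (18 keV microbeam, 320 s exposure): relative damaged volume Z by pinhole diameter, first-order accumulation rates, model fold-predictions for sub-micrometre beams, photoelectron tail attenuation length, and SHG imprint extents for a 20 um pinhole.",
  "z_320s_percent": {"100": 120.0, "20": 150.0, "10": 240.0, "5": 260.0},
  "k_percent_per_s": {"100": 0.33, "20": 0.07, "10": 0.02, "5": 0.02},
  "zeta_fold_subum": {"1": 10.0, "0.1": 75.0},
  "attenuation_length_um": 1.5,
  "shg_extents_320s_um": {
    "mineralized_h": 27.16,
    "mineralized_v": 22.13,
    "demineralized_h": 22.49,
    "demineralized_v": 16.24
  }
}
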