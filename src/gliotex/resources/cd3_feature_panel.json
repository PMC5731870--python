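{
 "name": "cd3_associated_t1post_panel",
 "description": "Frozen 6-feature panel associated with CD3 infiltration (all T1-post-contrast): histogram kurtosis, NGTDM contrast, and four GLSZM zone emphases.",
 "features": [
  "t1post_hist_kurtosis",
  "t1post_ngtdm_contrast",
  "t1post_glszm_small_zone_emphasis",
  "t1post_glszm_low_gray_level_zone_emphasis",
  "t1post_glszm_high_gray_level_zone_emphasis",
  "t1post_glszm_small_zone_high_gray_level_emphasis"
 ]
}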