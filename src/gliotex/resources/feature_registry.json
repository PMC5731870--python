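{
 "version": 1,
 "features": [
  "t1post_hist_mean",
  "t1post_hist_variance",
  "t1post_hist_skewness",
  "t1post_hist_kurtosis",
  "t1post_hist_entropy",
  "t1post_hist_uniformity",
  "t1post_gtsdm_energy",
  "t1post_gtsdm_contrast",
  "t1post_gtsdm_correlation",
  "t1post_gtsdm_sum_of_squares_variance",
  "t1post_gtsdm_homogeneity",
  "t1post_gtsdm_sum_average",
  "t1post_gtsdm_sum_variance",
  "t1post_gtsdm_sum_entropy",
  "t1post_gtsdm_entropy",
  "t1post_gtsdm_difference_variance",
  "t1post_gtsdm_difference_entropy",
  "t1post_gtsdm_imc1",
  "t1post_gtsdm_imc2",
  "t1post_gtsdm_autocorrelation",
  "t1post_gtsdm_cluster_shade",
  "t1post_gtsdm_cluster_prominence",
  "t1post_gtsdm_cluster_tendency",
  "t1post_gtsdm_dissimilarity",
  "t1post_gtsdm_maximum_probability",
  "t1post_ngtdm_coarseness",
  "t1post_ngtdm_contrast",
  "t1post_ngtdm_busyness",
  "t1post_ngtdm_complexity",
  "t1post_ngtdm_strength",
  "t1post_glszm_small_zone_emphasis",
  "t1post_glszm_large_zone_emphasis",
  "t1post_glszm_gray_level_nonuniformity",
  "t1post_glszm_zone_size_nonuniformity",
  "t1post_glszm_zone_percentage",
  "t1post_glszm_low_gray_level_zone_emphasis",
  "t1post_glszm_high_gray_level_zone_emphasis",
  "t1post_glszm_small_zone_low_gray_level_emphasis",
  "t1post_glszm_small_zone_high_gray_level_emphasis",
  "t1post_glszm_large_zone_low_gray_level_emphasis",
  "t1post_glszm_large_zone_high_gray_level_emphasis",
  "t1post_regional_tumor_volume_mm3",
  "t1post_regional_total_intensity",
  "flair_hist_mean",
  "flair_hist_variance",
  "flair_hist_skewness",
  "flair_hist_kurtosis",
  "flair_hist_entropy",
  "flair_hist_uniformity",
  "flair_gtsdm_energy",
  "flair_gtsdm_contrast",
  "flair_gtsdm_correlation",
  "flair_gtsdm_sum_of_squares_variance",
  "flair_gtsdm_homogeneity",
  "flair_gtsdm_sum_average",
  "flair_gtsdm_sum_variance",
  "flair_gtsdm_sum_entropy",
  "flair_gtsdm_entropy",
  "flair_gtsdm_difference_variance",
  "flair_gtsdm_difference_entropy",
  "flair_gtsdm_imc1",
  "flair_gtsdm_imc2",
  "flair_gtsdm_autocorrelation",
  "flair_gtsdm_cluster_shade",
  "flair_gtsdm_cluster_prominence",
  "flair_gtsdm_cluster_tendency",
  "flair_gtsdm_dissimilarity",
  "flair_gtsdm_maximum_probability",
  "flair_ngtdm_coarseness",
  "flair_ngtdm_contrast",
  "flair_ngtdm_busyness",
  "flair_ngtdm_complexity",
  "flair_ngtdm_strength",
  "flair_glszm_small_zone_emphasis",
  "flair_glszm_large_zone_emphasis",
  "flair_glszm_gray_level_nonuniformity",
  "flair_glszm_zone_size_nonuniformity",
  "flair_glszm_zone_percentage",
  "flair_glszm_low_gray_level_zone_emphasis",
  "flair_glszm_high_gray_level_zone_emphasis",
  "flair_glszm_small_zone_low_gray_level_emphasis",
  "flair_glszm_small_zone_high_gray_level_emphasis",
  "flair_glszm_large_zone_low_gray_level_emphasis",
  "flair_glszm_large_zone_high_gray_level_emphasis",
  "flair_regional_tumor_volume_mm3",
  "flair_regional_total_intensity"
 ]
}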