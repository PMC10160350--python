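# Species-specific frame-acceptance profiles.
#
# Each entry filters the largest detected object per frame: pixel-area range,
# fitted-ellipse length/width ratio range, minimum mean brightness (8-bit),
# minimum Laplacian-variance sharpness, minimum distance (px) from the object
# centre to the cuvette crop edge, and the calibrated percentile of the
# per-video length distribution reported as the size estimate.
#
# "daphnia" doubles as the default profile when no species is chosen.
# Add new taxa by appending entries here and re-running the percentile
# calibration for the mounted set-up.
daphnia:
  min_area_px: 1500
  max_area_px: 4000
  min_lw_ratio: 1.2
  max_lw_ratio: 1.7
  min_brightness: 30
  min_sharpness: 1.8
  min_edge_distance_px: 10
  optimal_percentile: 93
eucyclops_mesocyclops:
  min_area_px: 290
  max_area_px: 850
  min_lw_ratio: 1.3
  max_lw_ratio: 1.9
  min_brightness: 20
  min_sharpness: 1.8
  min_edge_distance_px: 10
  optimal_percentile: 90
diaphanosoma:
  min_area_px: 300
  max_area_px: 2500
  min_lw_ratio: 1.5
  max_lw_ratio: 2.5
  min_brightness: 20
  min_sharpness: 1.8
  min_edge_distance_px: 10
  optimal_percentile: 100
heterocope:
  min_area_px: 600
  max_area_px: 4000
  min_lw_ratio: 1.6
  max_lw_ratio: 2.2
  min_brightness: 20
  min_sharpness: 1.8
  min_edge_distance_px: 10
  optimal_percentile: 100
polyphemus:
  min_area_px: 250
  max_area_px: 1000
  min_lw_ratio: 1.0
  max_lw_ratio: 1.7
  min_brightness: 20
  min_sharpness: 1.8
  min_edge_distance_px: 10
  optimal_percentile: 98
scapholebrius:
  min_area_px: 250
  max_area_px: 1800
  min_lw_ratio: 1.0
  max_lw_ratio: 1.7
  min_brightness: 20
  min_sharpness: 1.8
  min_edge_distance_px: 10
  optimal_percentile: 96
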