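# Full synthetic-pipeline run: capitulum3d run --config examples/pipeline.yaml out/
seed: 0
interval_deg: 0.5
bud:
  n_florets: 90
  base_radius_px: 400.0
  apex_z: 460.0
  cone_half_angle_deg: 45.0
noise:
  jitter_sigma_px: 1.0
  p_miss: 0.1
  fp_rate: 0.5
image:
  width: 850
  height: 520
d_values: [1, 10, 20, 30, 40, 50]
d_estimate: 20.0
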