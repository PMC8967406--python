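# Example pipeline configuration for `chromashade run-all --config ...`.
# Any key omitted here falls back to the package default; flags override
# the file.
geometry:
  nx: 67
  amplitude: 0.5
  correlation_length: 3.0
  spacing: 0.25
photons:
  beam_n: 10000
  render_n: 1000000
analysis:
  resolution: 67
  report_elevations: [15, 45, 75]
observers:
  n: 11
  w_shading: 1.0
  w_curvature: 1.0
  w_saturation: 0.25
  sigma: 0.02
  lapse: 0.02
seed: 0
out_dir: runs/demo
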