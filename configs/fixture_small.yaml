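# Small smoke-test study: the dual-center design at n = 4 per center on a
# 24^3 grid, 12 respiratory phases. Runs end-to-end in seconds.
seed: 0
centers:
  - name: Center1
    n_subjects: 4
    profiles: [C1-1.5T, C1-3T]
  - name: Center2
    n_subjects: 4
    profiles: [C2-3T]
profiles:
  C1-1.5T: {field_strength: 1.5, snr: 500.0, heterogeneity_scale: 1.0}
  C1-3T: {field_strength: 3.0, snr: 320.0, heterogeneity_scale: 1.3}
  C2-3T: {field_strength: 3.0, snr: 320.0, heterogeneity_scale: 1.3}
grid:
  shape: [24, 24, 24]
  voxel_size: [8.0, 8.0, 8.0]
n_phases: 12
navigator_duration_s: 120.0
navigator_dt_s: 0.1
perturbation: {tidal_factor: 1.0, frequency_factor: 1.0}
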