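{
  "name": "hn_challenge_cohort",
  "version": "1.0",
  "note": "Per-field truncated-normal marginals (scale = reported SD, bounds = reported range, location solved so the truncated-normal median equals the reported median) plus the rank correlations the study text reports. The conformation row's printed SD rounds to 0.0 and its printed range minimum 0.7 contradicts the 4/14 plans reported in the 0.6-0.7 band; its scale and bounds are reconstructed to be consistent with the reported tier counts. Latent quality factors stand in for the downstream-computed PQM and PTV-points columns; their loadings spread plan quality across the metric targets.",
  "marginals": [
    {"field": "ptv1_d95", "kind": "metric", "mean": 67.5, "sd": 1.2, "median": 67.0, "min": 66.2, "max": 69.7},
    {"field": "ptv1_d0p1cc", "kind": "metric", "mean": 74.1, "sd": 1.3, "median": 73.9, "min": 72.0, "max": 76.6},
    {"field": "ptv2_d95", "kind": "metric", "mean": 59.0, "sd": 1.0, "median": 58.9, "min": 57.5, "max": 60.8},
    {"field": "ptv3_d95", "kind": "metric", "mean": 52.4, "sd": 0.8, "median": 52.6, "min": 50.7, "max": 53.5},
    {"field": "ptv3_minus_ptv2_v56p7", "kind": "metric", "mean": 22.3, "sd": 7.8, "median": 21.6, "min": 8.3, "max": 35.8},
    {"field": "ptv3_conformation", "kind": "metric", "mean": 0.705, "sd": 0.035, "median": 0.70, "min": 0.63, "max": 0.80},
    {"field": "spinal_canal_d0p1cc", "kind": "metric", "mean": 44.0, "sd": 2.4, "median": 43.4, "min": 39.0, "max": 48.8},
    {"field": "parotid_left_dmean", "kind": "metric", "mean": 22.0, "sd": 1.5, "median": 22.3, "min": 17.8, "max": 23.8},
    {"field": "parotid_right_dmean", "kind": "metric", "mean": 26.4, "sd": 1.4, "median": 26.0, "min": 24.4, "max": 29.1},
    {"field": "brainstem_d0p1cc", "kind": "metric", "mean": 42.1, "sd": 4.0, "median": 42.1, "min": 35.7, "max": 48.9},
    {"field": "brachial_plexus_d0p5cc", "kind": "metric", "mean": 51.2, "sd": 1.6, "median": 51.6, "min": 48.5, "max": 53.6},
    {"field": "brain_d0p1cc", "kind": "metric", "mean": 48.5, "sd": 2.9, "median": 49.7, "min": 43.2, "max": 52.4},
    {"field": "esophagus_d0p1cc", "kind": "metric", "mean": 44.5, "sd": 2.7, "median": 44.4, "min": 39.7, "max": 49.1},
    {"field": "glottis_dmean", "kind": "metric", "mean": 42.3, "sd": 1.9, "median": 42.9, "min": 39.1, "max": 44.9},
    {"field": "mandible_d0p1cc", "kind": "metric", "mean": 59.7, "sd": 2.4, "median": 59.5, "min": 56.9, "max": 64.8},
    {"field": "oral_cavity_dmean", "kind": "metric", "mean": 36.6, "sd": 3.5, "median": 36.0, "min": 32.6, "max": 44.9},
    {"field": "n_beams", "kind": "metadata", "mean": 21.1, "sd": 13.5, "median": 17.5, "min": 11, "max": 60, "integer": true},
    {"field": "n_segments", "kind": "metadata", "mean": 147.6, "sd": 24.2, "median": 139.0, "min": 114, "max": 208, "integer": true},
    {"field": "mu", "kind": "metadata", "mean": 918.9, "sd": 232.7, "median": 909.5, "min": 539, "max": 1474, "integer": true},
    {"field": "beam_on_min", "kind": "metadata", "mean": 1.5, "sd": 0.4, "median": 1.5, "min": 0.8, "max": 2.5},
    {"field": "delivery_min", "kind": "metadata", "mean": 18.7, "sd": 1.7, "median": 18.8, "min": 14.9, "max": 22.4},
    {"field": "experience_years", "kind": "metadata", "mean": 9.2, "sd": 6.9, "median": 7.0, "min": 2.0, "max": 20.0},
    {"field": "viewray_years", "kind": "metadata", "mean": 1.1, "sd": 0.6, "median": 1.0, "min": 0.0, "max": 2.0},
    {"field": "latent_pqm_quality", "kind": "latent"},
    {"field": "latent_ptv_quality", "kind": "latent"}
  ],
  "correlations": [
    {"field_a": "n_beams", "field_b": "n_segments", "rho": 0.67},
    {"field_a": "n_beams", "field_b": "mu", "rho": -0.63},
    {"field_a": "n_segments", "field_b": "latent_pqm_quality", "rho": 0.75},
    {"field_a": "n_segments", "field_b": "latent_ptv_quality", "rho": 0.76},
    {"field_a": "experience_years", "field_b": "spinal_canal_d0p1cc", "rho": -0.55},
    {"field_a": "experience_years", "field_b": "glottis_dmean", "rho": -0.55},
    {"field_a": "latent_ptv_quality", "field_b": "ptv1_d95", "rho": 0.4},
    {"field_a": "latent_ptv_quality", "field_b": "ptv1_d0p1cc", "rho": -0.4},
    {"field_a": "latent_ptv_quality", "field_b": "ptv2_d95", "rho": 0.4},
    {"field_a": "latent_ptv_quality", "field_b": "ptv3_d95", "rho": 0.4},
    {"field_a": "latent_ptv_quality", "field_b": "ptv3_minus_ptv2_v56p7", "rho": -0.4},
    {"field_a": "latent_ptv_quality", "field_b": "ptv3_conformation", "rho": 0.4},
    {"field_a": "latent_pqm_quality", "field_b": "parotid_left_dmean", "rho": -0.4},
    {"field_a": "latent_pqm_quality", "field_b": "parotid_right_dmean", "rho": -0.4},
    {"field_a": "latent_pqm_quality", "field_b": "brainstem_d0p1cc", "rho": -0.4},
    {"field_a": "latent_pqm_quality", "field_b": "brachial_plexus_d0p5cc", "rho": -0.4},
    {"field_a": "latent_pqm_quality", "field_b": "brain_d0p1cc", "rho": -0.4},
    {"field_a": "latent_pqm_quality", "field_b": "esophagus_d0p1cc", "rho": -0.4},
    {"field_a": "latent_pqm_quality", "field_b": "mandible_d0p1cc", "rho": -0.4},
    {"field_a": "latent_pqm_quality", "field_b": "oral_cavity_dmean", "rho": -0.4}
  ]
}
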