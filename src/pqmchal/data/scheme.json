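{
  "name": "hn_challenge_reconstructed",
  "version": "1.0",
  "note": "Reconstructed tier boundaries and weights: the challenge's exact scoring table was never published. Ideal thresholds follow the prescriptions (95%/107% coverage and hot-spot rules), conformation tiers the published 0.5/0.6/0.7/0.8 bands, OAR ideal thresholds the reported better/worse-than-ideal pattern, and hard bounds sit above the reported cohort maxima. Weights satisfy the 78 PTV + 72 OAR = 150 point scale.",
  "metrics": [
    {
      "metric_id": "ptv1_d95",
      "structure": "ptv1",
      "kind": "D_percent",
      "parameter": 95.0,
      "direction": "higher_better",
      "group": "PTV",
      "schedule": {"mode": "tiered", "boundaries": [63.0, 64.5, 65.5, 66.5], "tier_points": [0.0, 3.25, 6.5, 9.75, 13.0], "max_points": 13.0}
    },
    {
      "metric_id": "ptv1_d0p1cc",
      "structure": "ptv1",
      "kind": "D_cc",
      "parameter": 0.1,
      "direction": "lower_better",
      "group": "PTV",
      "schedule": {"mode": "tiered", "boundaries": [79.8, 78.0, 76.8, 74.9], "tier_points": [0.0, 3.25, 6.5, 9.75, 13.0], "max_points": 13.0}
    },
    {
      "metric_id": "ptv2_d95",
      "structure": "ptv2",
      "kind": "D_percent",
      "parameter": 95.0,
      "direction": "higher_better",
      "group": "PTV",
      "schedule": {"mode": "tiered", "boundaries": [53.5, 54.5, 55.5, 57.0], "tier_points": [0.0, 3.25, 6.5, 9.75, 13.0], "max_points": 13.0}
    },
    {
      "metric_id": "ptv3_d95",
      "structure": "ptv3",
      "kind": "D_percent",
      "parameter": 95.0,
      "direction": "higher_better",
      "group": "PTV",
      "schedule": {"mode": "tiered", "boundaries": [48.6, 49.5, 50.4, 51.3], "tier_points": [0.0, 3.25, 6.5, 9.75, 13.0], "max_points": 13.0}
    },
    {
      "metric_id": "ptv3_minus_ptv2_v56p7",
      "structure": "ptv3-ptv2",
      "kind": "V_gy_percent",
      "parameter": 56.7,
      "direction": "lower_better",
      "group": "PTV",
      "schedule": {"mode": "tiered", "boundaries": [45.0, 36.0, 28.0, 20.0], "tier_points": [0.0, 3.25, 6.5, 9.75, 13.0], "max_points": 13.0}
    },
    {
      "metric_id": "ptv3_conformation",
      "structure": "ptv3",
      "kind": "conformation",
      "parameter": 51.3,
      "direction": "higher_better",
      "group": "PTV",
      "schedule": {"mode": "tiered", "boundaries": [0.5, 0.6, 0.7, 0.8], "tier_points": [0.0, 3.25, 6.5, 9.75, 13.0], "max_points": 13.0}
    },
    {
      "metric_id": "spinal_canal_d0p1cc",
      "structure": "spinal_canal",
      "kind": "D_cc",
      "parameter": 0.1,
      "direction": "lower_better",
      "group": "OAR",
      "schedule": {"mode": "binary", "boundaries": [50.0], "tier_points": [0.0, 9.0], "max_points": 9.0}
    },
    {
      "metric_id": "parotid_left_dmean",
      "structure": "parotid_left",
      "kind": "D_mean",
      "parameter": null,
      "direction": "lower_better",
      "group": "OAR",
      "schedule": {"mode": "tiered", "boundaries": [28.0, 26.5, 25.0, 24.0], "tier_points": [0.0, 1.5, 3.0, 4.5, 6.0], "max_points": 6.0}
    },
    {
      "metric_id": "parotid_right_dmean",
      "structure": "parotid_right",
      "kind": "D_mean",
      "parameter": null,
      "direction": "lower_better",
      "group": "OAR",
      "schedule": {"mode": "tiered", "boundaries": [30.5, 29.0, 27.0, 25.0], "tier_points": [0.0, 1.5, 3.0, 4.5, 6.0], "max_points": 6.0}
    },
    {
      "metric_id": "brainstem_d0p1cc",
      "structure": "brainstem",
      "kind": "D_cc",
      "parameter": 0.1,
      "direction": "lower_better",
      "group": "OAR",
      "schedule": {"mode": "binary", "boundaries": [54.0], "tier_points": [0.0, 9.0], "max_points": 9.0}
    },
    {
      "metric_id": "brachial_plexus_d0p5cc",
      "structure": "brachial_plexus",
      "kind": "D_cc",
      "parameter": 0.5,
      "direction": "lower_better",
      "group": "OAR",
      "schedule": {"mode": "binary", "boundaries": [55.0], "tier_points": [0.0, 9.0], "max_points": 9.0}
    },
    {
      "metric_id": "brain_d0p1cc",
      "structure": "brain",
      "kind": "D_cc",
      "parameter": 0.1,
      "direction": "lower_better",
      "group": "OAR",
      "schedule": {"mode": "binary", "boundaries": [54.0], "tier_points": [0.0, 9.0], "max_points": 9.0}
    },
    {
      "metric_id": "esophagus_d0p1cc",
      "structure": "esophagus",
      "kind": "D_cc",
      "parameter": 0.1,
      "direction": "lower_better",
      "group": "OAR",
      "schedule": {"mode": "tiered", "boundaries": [50.0, 48.3, 46.6, 45.0], "tier_points": [0.0, 1.5, 3.0, 4.5, 6.0], "max_points": 6.0}
    },
    {
      "metric_id": "glottis_dmean",
      "structure": "glottis",
      "kind": "D_mean",
      "parameter": null,
      "direction": "lower_better",
      "group": "OAR",
      "schedule": {"mode": "tiered", "boundaries": [48.0, 46.5, 45.0, 43.5], "tier_points": [0.0, 1.5, 3.0, 4.5, 6.0], "max_points": 6.0}
    },
    {
      "metric_id": "mandible_d0p1cc",
      "structure": "mandible",
      "kind": "D_cc",
      "parameter": 0.1,
      "direction": "lower_better",
      "group": "OAR",
      "schedule": {"mode": "tiered", "boundaries": [66.0, 64.0, 62.0, 60.0], "tier_points": [0.0, 1.5, 3.0, 4.5, 6.0], "max_points": 6.0}
    },
    {
      "metric_id": "oral_cavity_dmean",
      "structure": "oral_cavity",
      "kind": "D_mean",
      "parameter": null,
      "direction": "lower_better",
      "group": "OAR",
      "schedule": {"mode": "tiered", "boundaries": [45.5, 42.0, 38.5, 35.0], "tier_points": [0.0, 1.5, 3.0, 4.5, 6.0], "max_points": 6.0}
    }
  ],
  "gates": {
    "max_delivery_min": 20.0,
    "hard_constraints": [
      {"metric_id": "ptv1_d95", "bound": 63.0, "direction": "ge"},
      {"metric_id": "ptv1_d0p1cc", "bound": 79.8, "direction": "le"},
      {"metric_id": "ptv2_d95", "bound": 53.5, "direction": "ge"},
      {"metric_id": "ptv3_d95", "bound": 48.6, "direction": "ge"},
      {"metric_id": "spinal_canal_d0p1cc", "bound": 50.0, "direction": "le"},
      {"metric_id": "brainstem_d0p1cc", "bound": 54.0, "direction": "le"},
      {"metric_id": "brachial_plexus_d0p5cc", "bound": 55.0, "direction": "le"},
      {"metric_id": "brain_d0p1cc", "bound": 54.0, "direction": "le"},
      {"metric_id": "esophagus_d0p1cc", "bound": 50.0, "direction": "le"},
      {"metric_id": "glottis_dmean", "bound": 48.0, "direction": "le"},
      {"metric_id": "mandible_d0p1cc", "bound": 66.0, "direction": "le"}
    ]
  }
}
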