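{
  "name": "hn_ellipsoid_phantom",
  "version": "1.0",
  "note": "Topological head-and-neck phantom: three nested ellipsoidal planning target volumes (simultaneous-integrated-boost levels 69.96 / 59.4 / 54 Gy in 33 fractions) with laterally placed parotids, a posterior midline spinal canal, superior brainstem and brain, inferior brachial plexus / esophagus / glottis, and anterior mandible / oral cavity. Geometry is configuration, not code; sizes in mm on a 160 mm cube at 2 mm voxels.",
  "grid_shape": [80, 80, 80],
  "spacing_mm": [2.0, 2.0, 2.0],
  "prescriptions_gy": {"ptv1": 69.96, "ptv2": 59.4, "ptv3": 54.0},
  "fractions": 33,
  "structures": [
    {"name": "ptv1", "shape": "ellipsoid", "center_mm": [80, 80, 80], "size_mm": [24, 20, 20]},
    {"name": "ptv2", "shape": "ellipsoid", "center_mm": [80, 80, 80], "size_mm": [36, 30, 30]},
    {"name": "ptv3", "shape": "ellipsoid", "center_mm": [80, 80, 80], "size_mm": [48, 32, 40]},
    {"name": "spinal_canal", "shape": "cylinder", "center_mm": [80, 135, 80], "size_mm": [5, 5, 60], "axis": 2},
    {"name": "parotid_left", "shape": "ellipsoid", "center_mm": [138, 80, 95], "size_mm": [9, 12, 14]},
    {"name": "parotid_right", "shape": "ellipsoid", "center_mm": [22, 80, 95], "size_mm": [9, 12, 14]},
    {"name": "brainstem", "shape": "ellipsoid", "center_mm": [80, 95, 131], "size_mm": [7, 7, 7]},
    {"name": "brachial_plexus", "shape": "cylinder", "center_mm": [80, 95, 30], "size_mm": [50, 4, 4], "axis": 0},
    {"name": "brain", "shape": "ellipsoid", "center_mm": [80, 85, 148], "size_mm": [30, 30, 10]},
    {"name": "esophagus", "shape": "cylinder", "center_mm": [80, 105, 25], "size_mm": [5, 5, 17], "axis": 2},
    {"name": "glottis", "shape": "ellipsoid", "center_mm": [80, 62, 28], "size_mm": [8, 8, 10]},
    {"name": "mandible", "shape": "box", "center_mm": [80, 24, 45], "size_mm": [35, 6, 7]},
    {"name": "oral_cavity", "shape": "ellipsoid", "center_mm": [80, 30, 70], "size_mm": [16, 11, 12]}
  ]
}
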