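{
  "schema_version": 1,
  "comment": "Editable musculoskeletal coefficients. Moment arms and orientations are polynomials in the relevant joint angle (radians, ascending coefficient order, metres / radians out). Values are documented placeholders in physiological ranges; substitute literature fits for production use.",
  "csa_cm2": {
    "gastrocnemius": 30.0,
    "soleus": 51.0,
    "hamstrings": 38.7,
    "gluteus_maximus": 43.7,
    "quadriceps": 89.0
  },
  "moment_arms": {
    "female": {
      "gastrocnemius_ankle": {"coeffs": [0.047, -0.006], "angle_range": [-0.7, 0.7]},
      "soleus_ankle": {"coeffs": [0.044, -0.005], "angle_range": [-0.7, 0.7]},
      "hamstrings_hip": {"coeffs": [0.060, 0.010], "angle_range": [-0.5, 1.2]},
      "gluteus_maximus_hip": {"coeffs": [0.064, 0.008], "angle_range": [-0.5, 1.2]},
      "quadriceps_knee": {"coeffs": [0.039, 0.009, -0.008], "angle_range": [0.0, 2.1]},
      "hamstrings_knee": {"coeffs": [0.024, 0.007, -0.004], "angle_range": [0.0, 2.1]},
      "gastrocnemius_knee": {"coeffs": [0.015, 0.004, -0.002], "angle_range": [0.0, 2.1]}
    },
    "male": {
      "gastrocnemius_ankle": {"coeffs": [0.049, -0.006], "angle_range": [-0.7, 0.7]},
      "soleus_ankle": {"coeffs": [0.046, -0.005], "angle_range": [-0.7, 0.7]},
      "hamstrings_hip": {"coeffs": [0.062, 0.010], "angle_range": [-0.5, 1.2]},
      "gluteus_maximus_hip": {"coeffs": [0.066, 0.008], "angle_range": [-0.5, 1.2]},
      "quadriceps_knee": {"coeffs": [0.042, 0.010, -0.009], "angle_range": [0.0, 2.1]},
      "hamstrings_knee": {"coeffs": [0.026, 0.008, -0.004], "angle_range": [0.0, 2.1]},
      "gastrocnemius_knee": {"coeffs": [0.016, 0.004, -0.002], "angle_range": [0.0, 2.1]}
    }
  },
  "knee_orientation": {
    "female": {
      "quadriceps": {"coeffs": [0.14, 0.05], "angle_range": [0.0, 2.1]},
      "hamstrings": {"coeffs": [0.22, 0.04], "angle_range": [0.0, 2.1]},
      "gastrocnemius": {"coeffs": [0.16, 0.03], "angle_range": [0.0, 2.1]},
      "acl": {"coeffs": [0.47, -0.10], "angle_range": [0.0, 2.1]},
      "pcl": {"coeffs": [0.57, -0.08], "angle_range": [0.0, 2.1]},
      "mcl": {"coeffs": [0.05], "angle_range": [0.0, 2.1]},
      "lcl": {"coeffs": [0.08], "angle_range": [0.0, 2.1]}
    },
    "male": {
      "quadriceps": {"coeffs": [0.12, 0.05], "angle_range": [0.0, 2.1]},
      "hamstrings": {"coeffs": [0.20, 0.04], "angle_range": [0.0, 2.1]},
      "gastrocnemius": {"coeffs": [0.15, 0.03], "angle_range": [0.0, 2.1]},
      "acl": {"coeffs": [0.45, -0.10], "angle_range": [0.0, 2.1]},
      "pcl": {"coeffs": [0.55, -0.08], "angle_range": [0.0, 2.1]},
      "mcl": {"coeffs": [0.05], "angle_range": [0.0, 2.1]},
      "lcl": {"coeffs": [0.08], "angle_range": [0.0, 2.1]}
    }
  },
  "frontal_arm_fraction": {
    "quadriceps": -0.5,
    "hamstrings": -0.5,
    "gastrocnemius": -0.5,
    "acl": -0.5,
    "pcl": -0.5,
    "mcl": -1.0,
    "lcl": 0.0
  },
  "condylar_ratio": {"female": 1.08, "male": 1.06},
  "heights": {
    "grand_mean_m": 1.69,
    "male_mean_m": 1.75,
    "female_mean_m": 1.628
  }
}
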