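{
  "version": 1,
  "description": "Three-patient neoadjuvant-chemotherapy cohort: clinical descriptors, measured CE-MRI lesion volumes, published model parameters and reference computed volumes.",
  "regimen_notes": "EC every 21 days x 4 cycles (days 0-63, block ends day 84), then weekly taxane-based therapy x 12 (days 84-161, block ends day 168); patient 1 additionally received trastuzumab with each paclitaxel dose. Infusions nominally 1 h.",
  "patients": [
    {
      "id": "patient1",
      "age": 60,
      "er_percent": 85,
      "pr_percent": 85,
      "ki67_percent": 22.5,
      "her2_positive": true,
      "v0_cm3": 4.2,
      "dvs_cm3": 0.18,
      "reference_v0_star_cm3": 4.07,
      "reference_dvs_star_cm3": 0.51,
      "params": {
        "d_c_m2_s": 1.0e-13,
        "d_d_m2_s": 1.0e-5,
        "r_c_per_s": 4.0e-7,
        "eps_pd_per_s": 3.64e-6,
        "eps_pk_per_hour": [2.0, 50.0, 50.0]
      },
      "drugs": [
        {"name": "EC", "first_dose_day": 0, "interval_days": 21, "count": 4},
        {"name": "paclitaxel", "first_dose_day": 84, "interval_days": 7, "count": 12},
        {"name": "trastuzumab", "first_dose_day": 84, "interval_days": 7, "count": 12}
      ]
    },
    {
      "id": "patient2",
      "age": 70,
      "er_percent": 90,
      "pr_percent": 45,
      "ki67_percent": 32.5,
      "her2_positive": false,
      "v0_cm3": 16.0,
      "dvs_cm3": 3.3,
      "reference_v0_star_cm3": 12.98,
      "reference_dvs_star_cm3": 3.37,
      "params": {
        "d_c_m2_s": 1.0e-13,
        "d_d_m2_s": 1.0e-5,
        "r_c_per_s": 5.7e-6,
        "eps_pd_per_s": 4.54e-4,
        "eps_pk_per_hour": [2.0, 50.0]
      },
      "drugs": [
        {"name": "EC", "first_dose_day": 0, "interval_days": 21, "count": 4},
        {"name": "paclitaxel", "first_dose_day": 84, "interval_days": 7, "count": 12}
      ]
    },
    {
      "id": "patient3",
      "age": 56,
      "er_percent": 85,
      "pr_percent": 85,
      "ki67_percent": 10,
      "her2_positive": false,
      "v0_cm3": 1.4,
      "dvs_cm3": 1.4,
      "reference_v0_star_cm3": 1.49,
      "reference_dvs_star_cm3": 1.58,
      "params": {
        "d_c_m2_s": 1.0e-13,
        "d_d_m2_s": 1.0e-5,
        "r_c_per_s": 6.0e-6,
        "eps_pd_per_s": 1.14e-6,
        "eps_pk_per_hour": [2.0, 50.0]
      },
      "drugs": [
        {"name": "EC", "first_dose_day": 0, "interval_days": 21, "count": 4},
        {"name": "paclitaxel", "first_dose_day": 84, "interval_days": 7, "count": 12}
      ]
    }
  ]
}
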