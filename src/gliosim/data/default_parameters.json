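{
  "_comment": "Default parameter set for the single astrocytic perisynaptic compartment model. Units are documented per key in the 'units' block. Values listed under '_calibrated' were tuned to reproduce the published characterization targets (resting levels, event amplitude regimes, sensor affinities, docked-pool recovery); everything else comes from the main-text values or canonical literature choices.",
  "model": {
    "vol_cyt_um3": 0.08,
    "er_cyt_volume_ratio": 0.15,
    "n_ip3r": 20,
    "ip3r_a1": 400.0,
    "ip3r_a2": 0.2,
    "ip3r_a3": 400.0,
    "ip3r_a4": 0.2,
    "ip3r_a5": 20.0,
    "ip3r_b1": 52.0,
    "ip3r_b2": 0.2098,
    "ip3r_b3": 377.36,
    "ip3r_b4": 0.0289,
    "ip3r_b5": 1.6468,
    "ip3r_flux_coeff": 12.0,
    "er_leak_rate": 0.15,
    "serca_vmax": 120.0,
    "serca_kd": 0.06,
    "pmca_vmax": 12.0,
    "pmca_kf": 150.0,
    "pmca_kb": 6.0,
    "pm_leak": 0.99,
    "buf_cyt_total": 45.0,
    "buf_cyt_kon": 50.0,
    "buf_cyt_koff": 500.0,
    "buf_er_total": 2000.0,
    "buf_er_kon": 1.0,
    "buf_er_koff": 200.0,
    "mglur_vmax": 1.2,
    "mglur_kd": 40.0,
    "mglur_hill": 1.0,
    "plcd_vmax": 0.2,
    "plcd_kd": 0.35,
    "ip3_5p_rate": 1.2,
    "ip3_3k_rate": 1.0,
    "ip3_3k_kd": 0.5,
    "rest_ca_cyt": 0.06,
    "rest_ca_er": 399.8,
    "rest_ip3": 0.0047
  },
  "sensors": {
    "syt4_kon": 20.0,
    "syt4_koff": 440.0,
    "syt4_fusion_rate": 12.0,
    "syt7_kon": 0.75,
    "syt7_koff": 11.25,
    "syt7_cooperativity": 0.55,
    "syt7_fusion_rate": 1.5
  },
  "pools": {
    "n_docked_init": 20,
    "n_mobile_init": 15,
    "docked_capacity": 20,
    "kr_endo_rate": 2.0,
    "kr_reacid_rate": 0.5,
    "ff_endo_rate": 0.25,
    "ff_reacid_rate": 0.1,
    "docking_rate": 0.12
  },
  "_calibrated": [
    "docking_rate",
    "er_leak_rate",
    "ff_endo_rate",
    "ff_reacid_rate",
    "ip3_5p_rate",
    "ip3r_flux_coeff",
    "kr_endo_rate",
    "kr_reacid_rate",
    "mglur_vmax",
    "n_docked_init",
    "n_mobile_init",
    "plcd_kd",
    "plcd_vmax",
    "pm_leak",
    "pmca_vmax",
    "serca_kd",
    "serca_vmax",
    "syt4_fusion_rate",
    "syt7_cooperativity",
    "syt7_fusion_rate"
  ],
  "units": {
    "vol_cyt_um3": "um^3, cytosolic volume of the process (bookkeeping only; the model is concentration-based)",
    "er_cyt_volume_ratio": "dimensionless, ER volume / cytosol volume, in (0, 1]",
    "n_ip3r": "count, IP3R channels in the ER cluster (each channel = 3 independent subunits)",
    "ip3r_a1": "1/(uM s), IP3 binding, inhibition site empty",
    "ip3r_a2": "1/(uM s), Ca binding to inhibition site, IP3 bound",
    "ip3r_a3": "1/(uM s), IP3 binding, inhibition site occupied",
    "ip3r_a4": "1/(uM s), Ca binding to inhibition site, IP3 unbound",
    "ip3r_a5": "1/(uM s), Ca binding to activation site",
    "ip3r_b1": "1/s, reverse of a1",
    "ip3r_b2": "1/s, reverse of a2",
    "ip3r_b3": "1/s, reverse of a3",
    "ip3r_b4": "1/s, reverse of a4",
    "ip3r_b5": "1/s, reverse of a5",
    "ip3r_flux_coeff": "1/s, maximal ER->cytosol flux coefficient with all channels open",
    "er_leak_rate": "1/s, passive ER->cytosol leak coefficient",
    "serca_vmax": "uM/s, maximal SERCA uptake (Hill n=2)",
    "serca_kd": "uM, SERCA half-activation",
    "pmca_vmax": "uM/s, maximal PMCA extrusion (Hill n=2)",
    "pmca_kf": "1/(uM^2 s), PMCA forward Ca-binding rate",
    "pmca_kb": "1/s, PMCA backward (unbinding) rate; operational affinity = sqrt(kb/kf)",
    "pm_leak": "uM/s, constant plasma-membrane Ca influx",
    "buf_cyt_total": "uM, total cytosolic buffer",
    "buf_cyt_kon": "1/(uM s), cytosolic buffer on-rate",
    "buf_cyt_koff": "1/s, cytosolic buffer off-rate",
    "buf_er_total": "uM, total ER buffer",
    "buf_er_kon": "1/(uM s), ER buffer on-rate",
    "buf_er_koff": "1/s, ER buffer off-rate",
    "mglur_vmax": "uM/s, maximal mGluR-driven IP3 production",
    "mglur_kd": "uM, agonist half-activation of mGluR IP3 production",
    "mglur_hill": "dimensionless, Hill slope of mGluR activation",
    "plcd_vmax": "uM/s, maximal PLCdelta IP3 production (Hill n=2 in Ca)",
    "plcd_kd": "uM, PLCdelta Ca half-activation",
    "ip3_5p_rate": "1/s, IP3 5-phosphatase first-order degradation",
    "ip3_3k_rate": "1/s, IP3 3-kinase maximal first-order degradation (Hill n=2 in Ca)",
    "ip3_3k_kd": "uM, 3-kinase Ca half-activation",
    "rest_ca_cyt": "uM, target resting cytosolic Ca (validation reference)",
    "rest_ca_er": "uM, target resting ER Ca (validation reference)",
    "rest_ip3": "uM, target resting IP3 (validation reference)",
    "syt4_kon": "1/(uM s), Syt4 Ca on-rate (single site, kd = koff/kon ~ 22 uM)",
    "syt4_koff": "1/s, Syt4 Ca off-rate",
    "syt4_fusion_rate": "1/s, kiss-and-run fusion rate from the Ca-bound Syt4 state, per docked vesicle",
    "syt7_kon": "1/(uM s), Syt7 per-site Ca on-rate (5 sites, per-site kd = koff/kon ~ 15 uM)",
    "syt7_koff": "1/s, Syt7 per-site Ca off-rate",
    "syt7_cooperativity": "dimensionless, factor multiplying the off-rate per successive bound site",
    "syt7_fusion_rate": "1/s, full-fusion rate from the fully bound Syt7 state, per mobile vesicle",
    "n_docked_init": "count, initial docked vesicles",
    "n_mobile_init": "count, initial mobile vesicles",
    "docked_capacity": "count, docking sites (docking halts when full)",
    "kr_endo_rate": "1/s, endocytosis rate after kiss-and-run release",
    "kr_reacid_rate": "1/s, reacidification rate on the kiss-and-run pathway",
    "ff_endo_rate": "1/s, endocytosis rate after full fusion",
    "ff_reacid_rate": "1/s, reacidification rate on the full-fusion pathway",
    "docking_rate": "1/s, mobile->docked transfer rate (per mobile vesicle, gated by free docking sites)"
  }
}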