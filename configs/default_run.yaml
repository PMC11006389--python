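# Pipeline configuration (all values shown are the package defaults).
# Load with divesat.RunConfig.from_yaml("configs/default_run.yaml").

odc:
  p50_mmHg: 36.0     # half-saturation pressure of the Hill curve
  hill_n: 2.9        # cooperativity exponent
  ph_ref: 7.5        # reference pH (informational; no Bohr correction)

blood:
  hb_g_dl: 18.0            # hemoglobin concentration
  o2_capacity_ml_g: 1.34   # ml O2 per g Hb at full saturation

surface_threshold_m: 2.0   # depth defining submergence
min_duration_min: 2.0      # strict dive-inclusion floor (> 2 min)
rate_threshold_m_s: 0.2    # smoothed vertical rate for descent/ascent
bottom_fraction: 0.9       # "at maximum depth" = depth >= 0.9 * max

inflection_threshold_pp: 4.0   # rise > 4 pp = positive inflection
plateau_min_duration_s: 30.0

landmark_declines: [2.5, 5.0, 10.0]

classifier:
  arterialized_floor_pct: 90.0
  sustained_decline_pp: 10.0
  late_onset_fraction: 0.5
  min_terminal_decline_pp: 2.0

adl_min: 5.6   # aerobic dive limit (minutes)
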