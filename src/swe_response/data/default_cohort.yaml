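# Default synthetic-cohort configuration.
#
# Targets are the published per-group, per-visit summaries of a 62-patient
# neoadjuvant-chemotherapy SWE study (34 responders / 28 non-responders):
# mean and SD of MRI volume (mm^3), mass size (mm), mean/maximum elasticity
# (kPa) and tumor-to-normal elasticity ratios, plus the number of patients
# with SWE and MRI data at each visit, Ki-67 moments, and subtype counts.
rho: 0.5                 # within-patient across-visit copula correlation
roi_min_frac: [0.7, 1.0] # V_min/V_mean of the tumor aggregate, uniform draw
pcr_fraction: 0.35       # responders with RCB = 0 (pathological complete response)
rcb_iii_fraction: 0.4    # non-surgical-complete non-responders in category III

groups:
  responder:
    n: 34
    n_no_surgery: 0
    ki67: {mean: 40.1, sd: 25.1, n_measured: 21}
    er_pos_pr_neg: 0     # ER+ patients reported PR-negative
    subtypes:
      luminal_a: 1
      luminal_b_her2neg: 8
      luminal_b_her2pos: 11
      her2_pos: 4
      tn: 9
      unclassified_fish_not_done: 1   # ER-/PR-, HER2 2+ without FISH
      unclassified_ki67_missing: 0    # ER+/HER2- with Ki-67 unavailable
      unclassified_er_neg_pr_pos: 0   # ER-/PR+ (outside the rule set)
    visits:
      1:
        n_swe: 28
        n_mri: 24
        mass_size: {mean: 27.1, sd: 13.7}
        e_mean: {mean: 82.2, sd: 38.0}
        e_max: {mean: 163.1, sd: 55.7}
        e_mean_ratio: {mean: 16.2, sd: 14.8}
        e_max_ratio: {mean: 16.6, sd: 14.0}
        v_mri: {mean: 104589.2, sd: 254548.7}
      2:
        n_swe: 32
        n_mri: 16
        mass_size: {mean: 16.5, sd: 8.5}
        e_mean: {mean: 38.5, sd: 22.7}
        e_max: {mean: 95.7, sd: 51.1}
        e_mean_ratio: {mean: 10.9, sd: 10.2}
        e_max_ratio: {mean: 14.3, sd: 15.1}
        v_mri: {mean: 24458.6, sd: 65700.82}
      3:
        n_swe: 25
        n_mri: 14
        mass_size: {mean: 10.6, sd: 6.6}
        e_mean: {mean: 29.5, sd: 25.4}
        e_max: {mean: 63.4, sd: 49.8}
        e_mean_ratio: {mean: 5.3, sd: 6.1}
        e_max_ratio: {mean: 6.1, sd: 5.5}
        v_mri: {mean: 16939.0, sd: 52964.8}
  nonresponder:
    n: 28
    n_no_surgery: 2      # progressed/deceased before surgery; non-responders
    ki67: {mean: 27.0, sd: 20.1, n_measured: 24}
    er_pos_pr_neg: 4
    subtypes:
      luminal_a: 7
      luminal_b_her2neg: 9
      luminal_b_her2pos: 5
      her2_pos: 2
      tn: 2
      unclassified_fish_not_done: 0
      unclassified_ki67_missing: 1
      unclassified_er_neg_pr_pos: 2
    visits:
      1:
        n_swe: 28
        n_mri: 25
        mass_size: {mean: 34.0, sd: 20.5}
        e_mean: {mean: 92.1, sd: 32.9}
        e_max: {mean: 179.6, sd: 38.6}
        e_mean_ratio: {mean: 26.0, sd: 21.2}
        e_max_ratio: {mean: 22.2, sd: 14.0}
        v_mri: {mean: 117407.7, sd: 164022.0}
      2:
        n_swe: 26
        n_mri: 7
        mass_size: {mean: 29.0, sd: 16.5}
        e_mean: {mean: 60.0, sd: 30.3}
        e_max: {mean: 134.9, sd: 59.0}
        e_mean_ratio: {mean: 16.8, sd: 14.9}
        e_max_ratio: {mean: 23.0, sd: 31.8}
        v_mri: {mean: 115921.4, sd: 131323.6}
      3:
        n_swe: 24
        n_mri: 14
        mass_size: {mean: 24.3, sd: 15.4}
        e_mean: {mean: 47.6, sd: 33.3}
        e_max: {mean: 114.3, sd: 72.9}
        e_mean_ratio: {mean: 10.8, sd: 9.8}
        e_max_ratio: {mean: 15.6, sd: 16.2}
        v_mri: {mean: 72912.7, sd: 123127.2}
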