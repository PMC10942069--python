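# Base-case parameters: one-year adjuvant trastuzumab vs chemotherapy alone,
# HER2+ early-stage breast cancer, Vietnam, 2020 VND, societal perspective.

[clinical]
hr_dfs = 0.760
hr_lrr = 0.580
hr_met = 0.480
p_lrr_base = 0.0294
p_met_base = 0.0785
p_dfs_after_lrr = 0.100
rr_met_after_lrr = 3.64
p_chf_trast = 0.198
p_chf_chemo = 0.007
p_death_met = 0.295

[utilities]
u_dfs = 0.832
u_lrr = 0.828
u_dfs_post_lrr = 0.789
u_dfs_chf = 0.670
u_met = 0.762

[costs]
trast_drug = 787384650
her2_detection = 686116
trast_other_direct_medical = 27040970
trast_direct_nonmedical = 5724180
paclitaxel_treatment = 32116418
c_dfs = 1400846
c_lrr = 216688208
c_dfs_post_lrr = 1400846
c_met = 131065482
c_dfs_chf = 9529840
p_440 = 45596775
p_150 = 15550710
trast_drug_sharing = 570022437

[settings]
start_age = 50
max_age = 100
cycle_length = 1
discount_rate = 0.03
benefit_duration = 5
recurrence_cutoff = 20
half_cycle_correction = false
exchange_rate = 22745
wtp_thresholds = 83000000, 249000000
patient_weight = 52.9
cohort_size = 5052
hr_transform = rate
drug_cost_mode = printed

[psa]
default_rel_range = 0.10
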