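"""Reference values shared by tests: published group summary statistics of the
study cohort this pipeline models, used as *inputs* to the summary-statistic
routines (means, SDs, implied group sizes, printed test statistics)."""

# scale -> (mean_nt, sd_nt, mean_asd, sd_asd, df, printed_t)
# group sizes are implied by the df given the reported missing questionnaires:
# df 58 -> 30/30, df 49 -> 29/22, df 47 -> 29/20
TABLE1 = {
    "IQ_matrices": (96.7, 14.5, 101.5, 16.7, 58, -1.20),
    "IQ_categories": (108.7, 12.9, 104.8, 19.5, 58, 0.90),
    "SCQ_total": (3.8, 2.4, 18.7, 8.1, 49, -9.41),
    "SCQ_social_interaction": (1.0, 0.9, 7.7, 4.0, 49, -8.82),
    "SCQ_communication": (1.9, 1.9, 6.5, 2.8, 49, -6.92),
    "SCQ_stereotypical": (0.8, 1.3, 4.1, 2.6, 49, -6.10),
    "CBCL_social_withdrawal": (51.8, 4.3, 62.9, 9.6, 47, -5.51),
    "CBCL_somatic": (53.1, 4.0, 56.5, 6.8, 47, -2.19),
    "CBCL_anxious_depressed": (51.7, 3.9, 56.7, 7.7, 47, -2.98),
    "CBCL_social_problems": (50.8, 3.4, 66.0, 8.4, 47, -8.71),
    "CBCL_thought_problems": (51.0, 2.7, 65.1, 11.9, 47, -6.15),
    "CBCL_attention": (51.3, 3.5, 63.0, 8.6, 47, -6.54),
    "CBCL_rule_breaking": (52.3, 5.5, 55.6, 6.3, 47, -1.95),
    "CBCL_aggressive": (51.0, 3.6, 58.4, 7.9, 47, -4.39),
}

GROUP_SIZES_BY_DF = {58: (30, 30), 49: (29, 22), 47: (29, 20)}

# parental education counts reconstructed from reported percentages x 60,
# no-information category dropped (N = 105): doctoral, university, college,
# 10 years, 9 years of formal education
EDUCATION_COUNTS = [
    [9, 26, 12, 12, 0],  # NT
    [2, 17, 6, 19, 2],  # ASD
]
EDUCATION_CHI2 = 10.47
EDUCATION_DF = 4
EDUCATION_N = 105

# (|Z|, printed r) of the leave-one-out rank-sum comparisons, n1 + n2 = 60
ZR_PAIRS = [
    (6.85, 0.88),
    (6.77, 0.87),
    (6.21, 0.80),
    (6.65, 0.86),
    (4.13, 0.53),
    (4.08, 0.53),
]
ZR_N_TOTAL = 60

# behavioral count model: fitted coefficients (log-odds)
BEHAVIOR_INTERCEPT = -3.26
BEHAVIOR_COUNT_SLOPE = 0.30
BEHAVIOR_INTERACTION = -0.09
BEHAVIOR_COUNT_OR = 1.35
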