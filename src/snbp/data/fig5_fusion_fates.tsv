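case	linkage	fate
# Fates of widely conserved genes after chromosomal fusions changed their
# linkage. Eight cases became sex-linked: two degenerated, one relocated
# back to an autosome (both recorded as degenerated_or_relocated) and five
# were retained. Sixteen cases stayed autosome-linked after a fusion and
# all sixteen were retained. The per-case margins (3:5 vs 0:16) are the
# published counts; individual case labels are descriptive only.
sex_case_01	sex	degenerated_or_relocated
sex_case_02	sex	degenerated_or_relocated
sex_case_03	sex	degenerated_or_relocated
sex_case_04	sex	retained
sex_case_05	sex	retained
sex_case_06	sex	retained
sex_case_07	sex	retained
sex_case_08	sex	retained
autosome_case_01	autosome	retained
autosome_case_02	autosome	retained
autosome_case_03	autosome	retained
autosome_case_04	autosome	retained
autosome_case_05	autosome	retained
autosome_case_06	autosome	retained
autosome_case_07	autosome	retained
autosome_case_08	autosome	retained
autosome_case_09	autosome	retained
autosome_case_10	autosome	retained
autosome_case_11	autosome	retained
autosome_case_12	autosome	retained
autosome_case_13	autosome	retained
autosome_case_14	autosome	retained
autosome_case_15	autosome	retained
autosome_case_16	autosome	retained
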