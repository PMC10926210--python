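# Default 17-SNP prothrombotic panel.
#
# risk_allele_freq: subcohort risk-allele frequency (mean of the women's and
# men's subcohort estimates, which agree to <0.005 everywhere).
# log_hr_female / log_hr_male: per-sex simulation log hazard ratios for
# carrier (>=1 risk allele) vs noncarrier, BMI-adjusted scale.
# coding_rule: minor_allele_risk | major_allele_risk | abo_deletion.
panel:
  - snp_id: rs1613662
    gene: GP6
    coding_rule: major_allele_risk
    risk_allele_freq: 0.826
    log_hr_female: -0.1054
    log_hr_male: 0.4824
  - snp_id: rs1801020
    gene: F12
    coding_rule: major_allele_risk
    risk_allele_freq: 0.744
    log_hr_female: 0.0392
    log_hr_male: -0.1165
  - snp_id: rs4524
    gene: F5
    coding_rule: major_allele_risk
    risk_allele_freq: 0.7285
    log_hr_female: 0.2390
    log_hr_male: 0.6780
  - snp_id: rs2036914
    gene: F11
    coding_rule: major_allele_risk
    risk_allele_freq: 0.5305
    log_hr_female: 0.2390
    log_hr_male: 0.1655
  - snp_id: rs1039084
    gene: STXBP5
    coding_rule: major_allele_risk
    risk_allele_freq: 0.515
    log_hr_female: 0.1398
    log_hr_male: 0.0296
  - snp_id: rs1884841
    gene: TC2N
    coding_rule: major_allele_risk
    risk_allele_freq: 0.4305
    log_hr_female: 0.1823
    log_hr_male: 0.0296
  - snp_id: rs710446
    gene: KNG1
    coding_rule: minor_allele_risk
    risk_allele_freq: 0.4125
    log_hr_female: 0.0677
    log_hr_male: -0.0305
  - snp_id: rs2289252
    gene: F11
    coding_rule: minor_allele_risk
    risk_allele_freq: 0.3915
    log_hr_female: 0.2469
    log_hr_male: 0.1740
  - snp_id: rs8176719
    gene: ABO
    coding_rule: abo_deletion
    risk_allele_freq: 0.3835
    log_hr_female: 0.2852
    log_hr_male: 0.3646
  - snp_id: rs1063857
    gene: VWF
    coding_rule: minor_allele_risk
    risk_allele_freq: 0.3815
    log_hr_female: 0.0488
    log_hr_male: 0.0100
  - snp_id: rs5985
    gene: F13
    coding_rule: minor_allele_risk
    risk_allele_freq: 0.2665
    log_hr_female: 0.0677
    log_hr_male: 0.1398
  - snp_id: rs2066865
    gene: FGG
    coding_rule: minor_allele_risk
    risk_allele_freq: 0.2395
    log_hr_female: 0.1398
    log_hr_male: 0.1823
  - snp_id: rs2227589
    gene: SERP
    coding_rule: minor_allele_risk
    risk_allele_freq: 0.0875
    log_hr_female: 0.1823
    log_hr_male: 0.0
  - snp_id: rs3813948
    gene: C4BPB
    coding_rule: minor_allele_risk
    risk_allele_freq: 0.0765
    log_hr_female: 0.0100
    log_hr_male: -0.0726
  - snp_id: rs6025
    gene: FVL
    coding_rule: minor_allele_risk
    risk_allele_freq: 0.034
    log_hr_female: 0.9083
    log_hr_male: 0.7747
  - snp_id: rs3136520
    gene: F2
    coding_rule: minor_allele_risk
    risk_allele_freq: 0.0305
    log_hr_female: -0.0513
    log_hr_male: 0.1484
  - snp_id: rs1799963
    gene: F2
    coding_rule: minor_allele_risk
    risk_allele_freq: 0.0065
    log_hr_female: 0.1570
    log_hr_male: 0.5822
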