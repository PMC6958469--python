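# Published treatment-over-control ratios (tumor volume, treated/vehicle) for the
# HER2-targeted thorium-227 conjugate +/- olaparib xenograft study, by tumor model.
# model: DLD-1 parental or DLD-1 BRCA2 knockout. Doses: single i.v. TTC dose in
# kBq/kg body weight; olaparib mg/kg daily i.p. for 4 weeks. significant: reported
# p < 0.05 vs vehicle (one-way ANOVA + Tukey). The low TTC dose is listed as 125
# kBq/kg here (the summary table's value); the running text also calls it 120 kBq/kg.
model,ttc_kbq_kg,olaparib_mg_kg,t_over_c,significant
parental,125,0,0.9,False
parental,300,0,0.5,True
parental,600,0,0.3,True
parental,0,25,0.6,False
parental,0,50,0.6,False
parental,125,25,0.8,False
parental,125,50,0.6,False
parental,300,25,0.4,True
parental,300,50,0.5,True
brca2_ko,125,0,0.8,False
brca2_ko,300,0,0.5,True
brca2_ko,600,0,0.1,True
brca2_ko,0,25,0.4,True
brca2_ko,0,50,0.5,True
brca2_ko,125,25,0.4,True
brca2_ko,125,50,0.1,True
brca2_ko,300,25,0.2,True
brca2_ko,300,50,0.03,True
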