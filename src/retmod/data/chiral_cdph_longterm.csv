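column,setpoint,analyte,predicted_rt,experimental_rt,experimental_rt_2y_first,experimental_rt_2y_last
chiral_cdph,3,ezetimibe_diol,19.05,18.32,19.27,19.31
chiral_cdph,3,thp_compound,22.37,21.89,22.72,22.81
chiral_cdph,3,rrs_ezetimibe,24.17,23.79,24.52,24.61
chiral_cdph,3,ezetimibe,25.74,25.20,25.99,26.09
chiral_cdph,3,ezetimibe_ketone,29.70,29.63,29.88,29.95
chiral_cdph,3,tbdms_ketone,33.93,34.68,34.27,34.36
chiral_cdph,3,benzylated_ezetimibe,35.15,35.34,35.38,35.48
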