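column,setpoint,analyte,predicted_rt,experimental_rt
chiral_cdph,1,ezetimibe_diol,22.22,20.48
chiral_cdph,1,thp_compound,27.76,26.46
chiral_cdph,1,rrs_ezetimibe,31.02,30.10
chiral_cdph,1,monofluoro_ezetimibe,32.38,31.22
chiral_cdph,1,ezetimibe,33.85,33.16
chiral_cdph,1,ezetimibe_ketone,41.13,40.78
chiral_cdph,1,tbdms_ketone,49.30,50.45
chiral_cdph,1,benzylated_ezetimibe,50.83,52.08
chiral_cdph,2,ezetimibe_diol,23.02,23.11
chiral_cdph,2,thp_compound,26.19,26.59
chiral_cdph,2,rrs_ezetimibe,28.07,28.51
chiral_cdph,2,ezetimibe,29.79,30.00
chiral_cdph,2,ezetimibe_ketone,34.06,34.19
chiral_cdph,2,tbdms_ketone,38.73,37.85
chiral_cdph,2,benzylated_ezetimibe,41.10,39.11
chiral_cdph,3,ezetimibe_diol,19.05,18.32
chiral_cdph,3,thp_compound,22.37,21.89
chiral_cdph,3,rrs_ezetimibe,24.17,23.79
chiral_cdph,3,ezetimibe,25.74,25.20
chiral_cdph,3,ezetimibe_ketone,29.70,29.63
chiral_cdph,3,tbdms_ketone,33.93,34.68
chiral_cdph,3,benzylated_ezetimibe,35.15,35.34
chiral_cdph,4,ezetimibe_diol,18.97,18.06
chiral_cdph,4,ezetimibe,23.96,23.60
chiral_cdph,4,ezetimibe_ketone,28.55,28.35
chiral_cdph,4,tbdms_ketone,37.13,37.62
chiral_cdph,4,benzylated_ezetimibe,34.76,35.07
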