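column,setpoint,analyte,predicted_rt,experimental_rt,experimental_rt_2y_first,experimental_rt_2y_last
chiralcel_od,1,ezetimibe_diol,23.72,25.73,25.57,25.65
chiralcel_od,1,desfluoro_ezetimibe,32.20,34.86,34.78,34.87
chiralcel_od,1,ezetimibe,33.97,36.16,35.99,36.06
chiralcel_od,1,thp_compound,35.79,38.17,37.91,37.98
chiralcel_od,1,ezetimibe_ketone,41.79,44.59,44.55,44.61
chiralcel_od,1,tbdms_ketone,56.38,58.33,58.30,58.36
chiralcel_od,1,benzylated_ezetimibe,63.41,65.94,65.75,65.81
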