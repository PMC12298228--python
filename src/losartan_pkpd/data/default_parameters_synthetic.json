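{
  "a": 2.0,
  "b": 2.0,
  "k_int_ent": 8.0,
  "k_ent_int": 101.8,
  "k_ent_cc": 10.0,
  "k_m": 2.817,
  "T": 0.5,
  "CL_m": 9.9,
  "Vm": 48.0,
  "CL_p": 23.8,
  "Vp_1": 20.0,
  "Q": 2.0,
  "Vp_2": 10.0,
  "k_int_ex": 0.0
}
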