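{
  "name": "benzene",
  "cas": "71-43-2",
  "risk_phrases": ["R45", "R46", "R11", "R48/23/24/25"],
  "iarc_group": "1",
  "acgih_class": "A1",
  "oral_ld50": 930,
  "inhal_lc50": 13700,
  "vapor_pressure_25c": 12.66,
  "boiling_point": 80.1,
  "pc_twa": 6.0,
  "pc_stel_limit": 12.0,
  "rfc": 0.03,
  "iur": 7.8e-06
}
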