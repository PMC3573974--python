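[
 {"type": "precedence", "name": "clb5_before_clb2", "group": "s_g2_checkpoint",
  "antecedent": {"node": "Clb5", "level": 1}, "consequent": {"node": "Clb2", "level": 1}},
 {"type": "precedence", "name": "clb2_before_cdc20", "group": "m_metaphase",
  "antecedent": {"node": "Clb2", "level": 1}, "consequent": {"node": "Cdc20", "level": 1}},
 {"type": "precedence", "name": "mcm1_before_cdc20", "group": "m_metaphase",
  "antecedent": {"node": "Mcm1", "level": 1}, "consequent": {"node": "Cdc20", "level": 1}},
 {"type": "response", "name": "cdc20_activates_swi5", "group": "m_telophase",
  "trigger": {"node": "Cdc20", "level": 1}, "obligation": {"node": "Swi5", "level": "max"}},
 {"type": "response", "name": "swi5_activates_sic1", "group": "m_telophase",
  "trigger": {"node": "Swi5", "level": "max"}, "obligation": {"node": "Sic1", "level": 1}},
 {"type": "response", "name": "cdc20_returns_to_g1", "group": "m_telophase",
  "trigger": {"node": "Cdc20", "level": 1}, "obligation": {"state": "stationary_g1"}},
 {"type": "global_attractor", "name": "g1_global_attractor", "group": "global",
  "target": "stationary_g1"}
]
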