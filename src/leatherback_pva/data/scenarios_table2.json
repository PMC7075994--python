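[
  {"label": "1 status quo"},
  {"label": "2 no relocation", "relocation": false},
  {"label": "3 harvest eradicated + increased emergence", "harvest_eradicated": true, "emergence_increase": 0.60},
  {"label": "4 harvest eradicated + head-start", "harvest_eradicated": true, "headstart_n": 50},
  {"label": "5 bycatch -5%", "bycatch_reduction": 0.05},
  {"label": "6 bycatch -10%", "bycatch_reduction": 0.10},
  {"label": "7 bycatch -20%", "bycatch_reduction": 0.20},
  {"label": "8 bycatch -5% + full nest protection", "bycatch_reduction": 0.05, "harvest_eradicated": true, "emergence_increase": 0.60},
  {"label": "9 bycatch -10% + full nest protection", "bycatch_reduction": 0.10, "harvest_eradicated": true, "emergence_increase": 0.60},
  {"label": "10 bycatch -20% + full nest protection", "bycatch_reduction": 0.20, "harvest_eradicated": true, "emergence_increase": 0.60}
]
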