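[
  {"label": "11 ramp delayed 10 yr", "schedule": [[1, 0.0], [11, 0.05], [16, 0.10], [21, 0.20]],
   "note": "preset, not published: 10 years status quo before the ramp"},
  {"label": "12 ramp delayed 5 yr", "schedule": [[1, 0.0], [6, 0.05], [11, 0.10], [16, 0.20]],
   "note": "published description: 5 years status quo, then 5-year blocks at 5%, 10%, 20%"},
  {"label": "13 immediate ramp", "schedule": [[1, 0.05], [6, 0.10], [11, 0.20]],
   "note": "preset, not published: ramp starts immediately"},
  {"label": "14 fast ramp", "schedule": [[1, 0.10], [6, 0.20]],
   "note": "preset, not published: 10% now, 20% after 5 years"}
]
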