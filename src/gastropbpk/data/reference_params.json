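{
  "dose": 1.85,
  "Rbp": 0.84,
  "V1": 302,
  "k1": 0.126,
  "k2": 0.0313,
  "CLtot": 56.9,
  "Ve": 0.441,
  "Vi": 0.401,
  "tissue_weight": 1.1,
  "Vstomach": 1.1,
  "fb_PSinf": 0.174,
  "Qt": 1.1,
  "VT": 0.133,
  "fu_PSeff": 0.006,
  "kass": 3.2e-05,
  "kdis": 4.85e-06,
  "IC50": 1.79,
  "kin": 0.00314,
  "kout": 0.00415
}
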