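{
  "vdw_radius": {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8
  },
  "lj": {
    "H": {"rmin_half": 0.6, "epsilon": 0.0157},
    "C": {"rmin_half": 1.908, "epsilon": 0.086},
    "N": {"rmin_half": 1.824, "epsilon": 0.17},
    "O": {"rmin_half": 1.6612, "epsilon": 0.21},
    "S": {"rmin_half": 2.0, "epsilon": 0.25},
    "P": {"rmin_half": 2.1, "epsilon": 0.2}
  },
  "coulomb_constant": 332.0636
}
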