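{
  "name": "brw",
  "n_sites": 4,
  "conformations": [
    {
      "name": "B",
      "L": 1.0,
      "K": 0.0009
    },
    {
      "name": "S",
      "L": 2.867,
      "K": 0.004
    },
    {
      "name": "M",
      "L": 207.5,
      "K": 4.97e-05
    },
    {
      "name": "L",
      "L": 1000000.0,
      "K": 5.02e-06
    }
  ]
}
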