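{
  "name": "iw",
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
      "K": 0.001
    },
    {
      "name": "M",
      "L": 207.5,
      "K": 8.58e-05
    },
    {
      "name": "L",
      "L": 1000000.0,
      "K": 1.198e-05
    }
  ]
}
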