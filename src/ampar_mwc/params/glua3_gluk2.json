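{
  "name": "glua3_gluk2",
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
      "K": 5.407e-05
    },
    {
      "name": "M",
      "L": 207.5,
      "K": 3.33e-06
    },
    {
      "name": "L",
      "L": 1000000.0,
      "K": 2.298e-07
    }
  ]
}
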