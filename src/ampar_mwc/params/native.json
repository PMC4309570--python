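{
  "name": "native",
  "n_sites": 4,
  "conformations": [
    {
      "name": "B",
      "L": 1.0,
      "K": null
    },
    {
      "name": "S",
      "L": 20.387,
      "K": 0.001
    },
    {
      "name": "M",
      "L": 28.898,
      "K": 0.00037
    },
    {
      "name": "L",
      "L": 1066.73,
      "K": 0.0001
    }
  ]
}
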