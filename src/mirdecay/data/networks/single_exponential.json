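{
  "name": "single_exponential",
  "states": [
    "0"
  ],
  "initial": "0",
  "edges": [
    {
      "from": "0",
      "to": "sink",
      "rate": "mu"
    }
  ],
  "rates": {
    "mu": 0.0276
  }
}
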