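{
  "name": "control_negative",
  "states": [
    "0",
    "1"
  ],
  "initial": "0",
  "edges": [
    {
      "from": "0",
      "to": "sink",
      "rate": "mu"
    },
    {
      "from": "0",
      "to": "1",
      "rate": "lambda"
    },
    {
      "from": "1",
      "to": "sink",
      "rate": "nu"
    }
  ],
  "rates": {
    "lambda": 0.0008,
    "mu": 0.0276,
    "nu": 0.0028
  }
}
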