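{
  "name": "control_positive",
  "states": [
    "0",
    "1",
    "2"
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
    },
    {
      "from": "0",
      "to": "2",
      "rate": "lambda_RNP"
    },
    {
      "from": "2",
      "to": "sink",
      "rate": "mu_RNP"
    }
  ],
  "rates": {
    "lambda_RNP": 0.1501,
    "mu_RNP": 0.0493,
    "nu": 0.0028,
    "mu": 0.0276,
    "lambda": 0.0008
  }
}
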