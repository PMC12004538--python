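{
  "H": [1.4870, 0.0157],
  "C": [1.9080, 0.0860],
  "N": [1.8240, 0.1700],
  "O": [1.6612, 0.2100],
  "S": [2.0000, 0.2500],
  "F": [1.7500, 0.0610],
  "Cl": [1.9480, 0.2650],
  "Br": [2.0200, 0.4200],
  "P": [2.1000, 0.2000]
}
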