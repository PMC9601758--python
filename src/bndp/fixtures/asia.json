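{
 "name": "asia",
 "comment": "8-node binary chest-clinic benchmark with its canonical CPTs; state 0 = no, 1 = yes.",
 "variables": [
  {"name": "asia", "cardinality": 2},
  {"name": "tub", "cardinality": 2},
  {"name": "smoke", "cardinality": 2},
  {"name": "lung", "cardinality": 2},
  {"name": "bronc", "cardinality": 2},
  {"name": "either", "cardinality": 2},
  {"name": "xray", "cardinality": 2},
  {"name": "dysp", "cardinality": 2}
 ],
 "edges": [
  ["asia", "tub"],
  ["smoke", "lung"],
  ["smoke", "bronc"],
  ["tub", "either"],
  ["lung", "either"],
  ["either", "xray"],
  ["bronc", "dysp"],
  ["either", "dysp"]
 ],
 "cpts": {
  "asia": [[0.99, 0.01]],
  "tub": [[0.99, 0.01], [0.95, 0.05]],
  "smoke": [[0.5, 0.5]],
  "lung": [[0.99, 0.01], [0.9, 0.1]],
  "bronc": [[0.7, 0.3], [0.4, 0.6]],
  "either": [[1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [0.0, 1.0]],
  "xray": [[0.95, 0.05], [0.02, 0.98]],
  "dysp": [[0.9, 0.1], [0.3, 0.7], [0.2, 0.8], [0.1, 0.9]]
 }
}
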