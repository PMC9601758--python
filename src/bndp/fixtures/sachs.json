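{
 "name": "sachs",
 "comment": "11-node protein-signalling consensus structure (3 states per variable). CPTs are NOT embedded: the loader synthesizes a seed-pinned Dirichlet stand-in (synthetic CPTs), only the structure is authentic. Variable order matches the benchmark's causal layering.",
 "variables": [
  {"name": "PKC", "cardinality": 3},
  {"name": "PKA", "cardinality": 3},
  {"name": "Raf", "cardinality": 3},
  {"name": "Mek", "cardinality": 3},
  {"name": "Erk", "cardinality": 3},
  {"name": "Akt", "cardinality": 3},
  {"name": "Jnk", "cardinality": 3},
  {"name": "P38", "cardinality": 3},
  {"name": "Plcg", "cardinality": 3},
  {"name": "PIP3", "cardinality": 3},
  {"name": "PIP2", "cardinality": 3}
 ],
 "edges": [
  ["PKC", "PKA"],
  ["PKC", "Raf"],
  ["PKC", "Mek"],
  ["PKC", "Jnk"],
  ["PKC", "P38"],
  ["PKA", "Raf"],
  ["PKA", "Mek"],
  ["PKA", "Erk"],
  ["PKA", "Akt"],
  ["PKA", "Jnk"],
  ["PKA", "P38"],
  ["Raf", "Mek"],
  ["Mek", "Erk"],
  ["Erk", "Akt"],
  ["Plcg", "PIP3"],
  ["Plcg", "PIP2"],
  ["PIP3", "PIP2"]
 ]
}
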