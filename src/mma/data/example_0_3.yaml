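# abba : abab :: pqrrqp : ?   (answer pqrpqr)
name: example_0_3
variables: [x1, x2]
source:
  context: strings
  pi:
    - "lambda(x1, x2)"
    - "lambda(x1, sigma(x2))"
  generators: [ab]
target:
  context: strings
  psi:
    - "lambda(x1, x2)"
    - "lambda(x1, sigma(x2))"
  generators: [pqr]
translation:
  "lambda(x1, x2)": "lambda(x1, x2)"
  "lambda(x1, sigma(x2))": "lambda(x1, sigma(x2))"
generator_map:
  ab: pqr
items: {a: abba, b: abab, c: pqrrqp}
bounds: {depth: 2}
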