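# abba : abbbbba :: pqrrpq : ?   (answer pqrrrrrpq)
name: example_0_4
variables: [x1, x2]
source:
  context: strings
  pi:
    - "lambda(lambda(x1, x2), lambda(x2, x1))"
    - "lambda(lambda(lambda(lambda(lambda(x1, x2), x2), x2), x2), lambda(x2, x1))"
  generators: [a, b]
target:
  context: strings
  psi:
    - "lambda(lambda(x1, x2), lambda(x2, x1))"
    - "lambda(lambda(lambda(lambda(lambda(x1, x2), x2), x2), x2), lambda(x2, x1))"
  generators: [pq, r]
translation:
  "lambda(lambda(x1, x2), lambda(x2, x1))": "lambda(lambda(x1, x2), lambda(x2, x1))"
  "lambda(lambda(lambda(lambda(lambda(x1, x2), x2), x2), x2), lambda(x2, x1))": "lambda(lambda(lambda(lambda(lambda(x1, x2), x2), x2), x2), lambda(x2, x1))"
generator_map:
  a: pq
  b: r
items: {a: abba, b: abbbbba, c: pqrrpq}
bounds: {depth: 2}
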