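# ababa : abbaa :: cdcdg : ?   (no F-homomorphism exists)
name: example_0_6
variables: [x1, x2]
source:
  context: strings
  pi:
    - "lambda(lambda(x1, x1), x2)"
    - "lambda(lambda(x1, sigma(x1)), x2)"
  generators: [ab, a]
target:
  context: strings
  psi:
    - "lambda(lambda(x1, x1), x2)"
    - "lambda(lambda(x1, sigma(x1)), x2)"
  generators: [cd, g]
translation:
  "lambda(lambda(x1, x1), x2)": "lambda(lambda(x1, x1), x2)"
  "lambda(lambda(x1, sigma(x1)), x2)": "lambda(lambda(x1, sigma(x1)), x2)"
generator_map:
  ab: cd
  a: g
items: {a: ababa, b: abbaa, c: cdcdg}
bounds: {depth: 2}
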