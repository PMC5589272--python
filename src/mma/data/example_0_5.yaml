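# aabc : aabd :: ijkk : ?   (intended copycat answer hjkk)
name: example_0_5
variables: [x1, x2, x3]
source:
  context: strings_succ
  pi:
    - "lambda(x1, x2)"
    - "suc(x3)"
  generators: [a]
target:
  context: strings_succ
  psi:
    - "lambda(x2, x1)"
    - "pre(x3)"
  generators: [k]
translation:
  "lambda(x1, x2)": "lambda(x2, x1)"
  "suc(x3)": "pre(x3)"
generator_map:
  a: k
items: {a: aabc, b: aabd, c: ijkk}
bounds: {depth: 4}
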