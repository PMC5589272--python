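# abc : abd :: kji : ?   (two modelings: answers kjh and lji)
name: example_0_7
variables: [x1, x2, x3]
items: {a: abc, b: abd, c: kji}
bounds: {depth: 4}
modelings:
  - name: modeling_1
    source:
      context: strings_succ
      pi:
        - "lambda(x1, x2)"
        - "suc(x3)"
      generators: [a]
    target:
      context: strings_succ
      psi:
        - "lambda(x1, x2)"
        - "pre(x3)"
      generators: [k]
    translation:
      "lambda(x1, x2)": "lambda(x1, x2)"
      "suc(x3)": "pre(x3)"
    generator_map:
      a: k
  - name: modeling_2
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
        - "suc(x3)"
      generators: [i]
    translation:
      "lambda(x1, x2)": "lambda(x2, x1)"
      "suc(x3)": "suc(x3)"
    generator_map:
      a: i
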