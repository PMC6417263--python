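variables:
- name: landscape
  terms:
  - low
  - medium low
  - medium high
  - high
  nodes:
  - 0.0
  - 0.3333333333333333
  - 0.6666666666666666
  - 1.0
  domain:
  - 0.0
  - 1.0
- name: wind
  terms:
  - comfortable
  - high
  - too high
  nodes:
  - 3.0
  - 3.7
  - 4.7
  domain:
  - 0.0
  - 12.0
- name: climate
  terms:
  - bad
  - medium bad
  - medium good
  - good
  nodes:
  - 0.0
  - 0.3333333333333333
  - 0.6666666666666666
  - 1.0
  domain:
  - 0.0
  - 1.0
output:
  labels:
  - bbbb
  - bbb
  - bb
  - b
  - m
  - g
  - gg
  - ggg
  - gggg
  singletons:
  - 0.0
  - 0.125
  - 0.25
  - 0.375
  - 0.5
  - 0.625
  - 0.75
  - 0.875
  - 1.0
rules:
- landscape: low
  wind: comfortable
  climate: bad
  then: bbbb
- landscape: low
  wind: comfortable
  climate: medium bad
  then: bbb
- landscape: low
  wind: comfortable
  climate: medium good
  then: bb
- landscape: low
  wind: comfortable
  climate: good
  then: b
- landscape: low
  wind: high
  climate: bad
  then: bbbb
- landscape: low
  wind: high
  climate: medium bad
  then: bbbb
- landscape: low
  wind: high
  climate: medium good
  then: bbb
- landscape: low
  wind: high
  climate: good
  then: bbb
- landscape: low
  wind: too high
  climate: bad
  then: bbbb
- landscape: low
  wind: too high
  climate: medium bad
  then: bbbb
- landscape: low
  wind: too high
  climate: medium good
  then: bbbb
- landscape: low
  wind: too high
  climate: good
  then: bbb
- landscape: medium low
  wind: comfortable
  climate: bad
  then: bb
- landscape: medium low
  wind: comfortable
  climate: medium bad
  then: b
- landscape: medium low
  wind: comfortable
  climate: medium good
  then: m
- landscape: medium low
  wind: comfortable
  climate: good
  then: g
- landscape: medium low
  wind: high
  climate: bad
  then: bbb
- landscape: medium low
  wind: high
  climate: medium bad
  then: bb
- landscape: medium low
  wind: high
  climate: medium good
  then: m
- landscape: medium low
  wind: high
  climate: good
  then: m
- landscape: medium low
  wind: too high
  climate: bad
  then: bbbb
- landscape: medium low
  wind: too high
  climate: medium bad
  then: bbbb
- landscape: medium low
  wind: too high
  climate: medium good
  then: bbb
- landscape: medium low
  wind: too high
  climate: good
  then: bbb
- landscape: medium high
  wind: comfortable
  climate: bad
  then: m
- landscape: medium high
  wind: comfortable
  climate: medium bad
  then: gg
- landscape: medium high
  wind: comfortable
  climate: medium good
  then: ggg
- landscape: medium high
  wind: comfortable
  climate: good
  then: gggg
- landscape: medium high
  wind: high
  climate: bad
  then: bb
- landscape: medium high
  wind: high
  climate: medium bad
  then: m
- landscape: medium high
  wind: high
  climate: medium good
  then: g
- landscape: medium high
  wind: high
  climate: good
  then: gg
- landscape: medium high
  wind: too high
  climate: bad
  then: bbbb
- landscape: medium high
  wind: too high
  climate: medium bad
  then: bbb
- landscape: medium high
  wind: too high
  climate: medium good
  then: bb
- landscape: medium high
  wind: too high
  climate: good
  then: bb
- landscape: high
  wind: comfortable
  climate: bad
  then: m
- landscape: high
  wind: comfortable
  climate: medium bad
  then: gg
- landscape: high
  wind: comfortable
  climate: medium good
  then: gggg
- landscape: high
  wind: comfortable
  climate: good
  then: gggg
- landscape: high
  wind: high
  climate: bad
  then: bb
- landscape: high
  wind: high
  climate: medium bad
  then: m
- landscape: high
  wind: high
  climate: medium good
  then: gg
- landscape: high
  wind: high
  climate: good
  then: ggg
- landscape: high
  wind: too high
  climate: bad
  then: bbbb
- landscape: high
  wind: too high
  climate: medium bad
  then: bbb
- landscape: high
  wind: too high
  climate: medium good
  then: bb
- landscape: high
  wind: too high
  climate: good
  then: bb
tnorm: prod
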