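schema: allonet-model/1
structures:
- name: A
  root:
    name: c
    allosteric: true
    conformations:
    - R
    - T
    sites:
    - name: X
      kind: binding
    - name: Y
      kind: binding
    couplings:
    - modifier: c.X
      phi: 0.5
    - modifier: c.Y
      phi: 0.5
- name: X
  root:
    name: c
    sites:
    - name: b
      kind: binding
- name: Y
  root:
    name: c
    sites:
    - name: b
      kind: binding
allosteric:
  A.c:
    K0: 0.001
    kf0: 1.0
rules:
- name: X-A(R)
  a:
    site: X.c.b
  b:
    site: A.c.X
    conf:
      .: R
  kf: 0.1
  kb: 1.0
- name: X-A(T)
  a:
    site: X.c.b
  b:
    site: A.c.X
    conf:
      .: T
  kf: 10.0
  kb: 1.0
- name: Y-A(R)
  a:
    site: Y.c.b
  b:
    site: A.c.Y
    conf:
      .: R
  kf: 0.01
  kb: 1.0
- name: Y-A(T)
  a:
    site: Y.c.b
  b:
    site: A.c.Y
    conf:
      .: T
  kf: 100.0
  kb: 1.0
init:
  A: 1.0
  X: 0.0
  Y: 1.0
probes:
  bound_Y:
  - structure: Y
    bound:
      Y.c.b: true
    weight: 1.0
  bound_X:
  - structure: X
    bound:
      X.c.b: true
    weight: 1.0
  trimer:
  - structure: A
    bound:
      A.c.X: true
      A.c.Y: true
    weight: 1.0
  total_A:
  - structure: A
    weight: 1.0
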