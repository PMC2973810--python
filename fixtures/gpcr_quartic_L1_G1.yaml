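schema: allonet-model/1
structures:
- name: R
  root:
    name: c
    sites:
    - name: LB
      kind: binding
    - name: GB
      kind: binding
    children:
    - name: ED
      allosteric: true
      conformations:
      - s
      - t
      couplings:
      - modifier: c.LB
        phi: 0.5
      - modifier: c.GB
        phi: 0.5
      - modifier: c.ID
        gamma: 1.0
        phi: 0.5
    - name: ID
      allosteric: true
      conformations:
      - i
      - a
      couplings:
      - modifier: c.LB
        phi: 0.5
      - modifier: c.GB
        phi: 0.5
      - modifier: c.ED
        gamma: 1.0
        phi: 0.5
- name: L1
  root:
    name: c
    sites:
    - name: b
      kind: binding
- name: G1
  root:
    name: c
    sites:
    - name: b
      kind: binding
allosteric:
  R.c.ED:
    K0: 1.0
    kf0: 1.0
  R.c.ID:
    K0: 0.05
    kf0: 1.0
rules:
- name: L1(si)
  a:
    site: L1.c.b
  b:
    site: R.c.LB
    conf:
      R.c.ED: s
      R.c.ID: i
  kf: 10.0
  kb: 1.0
- name: L1(ti)
  a:
    site: L1.c.b
  b:
    site: R.c.LB
    conf:
      R.c.ED: t
      R.c.ID: i
  kf: 1.0
  kb: 1.0
- name: L1(sa)
  a:
    site: L1.c.b
  b:
    site: R.c.LB
    conf:
      R.c.ED: s
      R.c.ID: a
  kf: 100.0
  kb: 1.0
- name: L1(ta)
  a:
    site: L1.c.b
  b:
    site: R.c.LB
    conf:
      R.c.ED: t
      R.c.ID: a
  kf: 10.0
  kb: 1.0
- name: G1(si)
  a:
    site: G1.c.b
  b:
    site: R.c.GB
    conf:
      R.c.ED: s
      R.c.ID: i
  kf: 10.0
  kb: 1.0
- name: G1(ti)
  a:
    site: G1.c.b
  b:
    site: R.c.GB
    conf:
      R.c.ED: t
      R.c.ID: i
  kf: 1.0
  kb: 1.0
- name: G1(sa)
  a:
    site: G1.c.b
  b:
    site: R.c.GB
    conf:
      R.c.ED: s
      R.c.ID: a
  kf: 100.0
  kb: 1.0
- name: G1(ta)
  a:
    site: G1.c.b
  b:
    site: R.c.GB
    conf:
      R.c.ED: t
      R.c.ID: a
  kf: 10.0
  kb: 1.0
init:
  R: 1.0
  L1: 0.0
  G1: 1.0
probes:
  signalling:
  - structure: R
    conf:
      R.c.ID: a
    bound:
      R.c.GB: true
    weight: 1.0
  active:
  - structure: R
    conf:
      R.c.ID: a
    weight: 1.0
  total_R:
  - structure: R
    weight: 1.0
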