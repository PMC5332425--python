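groups:
  G1:
    n: 113
    variables:
    - pr1_t1
    - pr2_t1
    - pr1_t2
    - pr2_t2
    means:
    - 3.44
    - 3.49
    - 3.62
    - 3.71
    sds:
    - 0.75
    - 0.72
    - 0.6
    - 0.62
    correlations:
    - - 1.0
    - - 0.81
      - 1.0
    - - 0.51
      - 0.52
      - 1.0
    - - 0.48
      - 0.59
      - 0.78
      - 1.0
  G2:
    n: 91
    variables:
    - pr1_t1
    - pr2_t1
    - pr1_t2
    - pr2_t2
    means:
    - 3.42
    - 3.49
    - 3.49
    - 3.55
    sds:
    - 0.7
    - 0.71
    - 0.65
    - 0.64
    correlations:
    - - 1.0
    - - 0.76
      - 1.0
    - - 0.74
      - 0.67
      - 1.0
    - - 0.65
      - 0.73
      - 0.78
      - 1.0
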