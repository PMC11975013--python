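config:
  eaa_list:
  - Ile
  - Leu
  - Lys
  - Phe
  - Thr
  - Val
  endmember_means:
    bacteria:
      Ile: -17.0
      Leu: -21.5
      Lys: -14.0
      Phe: -22.0
      Thr: -9.5
      Val: -18.5
    fungi:
      Ile: -22.5
      Leu: -26.5
      Lys: -19.5
      Phe: -26.5
      Thr: -14.5
      Val: -24.0
    plants:
      Ile: -27.5
      Leu: -31.0
      Lys: -25.0
      Phe: -29.0
      Thr: -22.5
      Val: -29.0
  endmember_cov:
    bacteria: 1.0
    fungi: 1.0
    plants: 1.0
  n_per_endmember_class:
    bacteria: 12
    fungi: 9
    plants: 11
  diet_new:
    Ile: -23.5
    Leu: -28.0
    Lys: -21.5
    Phe: -27.5
    Thr: -17.5
    Val: -25.5
  diet_old:
    Ile: -16.5
    Leu: -21.0
    Lys: -14.5
    Phe: -20.5
    Thr: -10.5
    Val: -18.5
  microbe_source:
    Ile: -17.0
    Leu: -21.5
    Lys: -14.0
    Phe: -22.0
    Thr: -9.5
    Val: -18.5
  turnover:
    liver: 0.75
    kidney: 0.6
    muscle: 0.45
    brain: 0.3
  f_microbial:
    GF: 0.0
    CVZ: 0.0
  trophic_offset: {}
  noise_sd: 0.2
  n_per_group: 5
  replicates_per_sample: 2
  n_diet_samples: 2
  seed: 0
expected:
  GF:brain:
  - -18.6
  - -23.1
  - -16.6
  - -22.6
  - -12.6
  - -20.6
  GF:kidney:
  - -20.7
  - -25.2
  - -18.7
  - -24.7
  - -14.7
  - -22.7
  GF:liver:
  - -21.75
  - -26.25
  - -19.75
  - -25.75
  - -15.75
  - -23.75
  GF:muscle:
  - -19.65
  - -24.15
  - -17.65
  - -23.65
  - -13.65
  - -21.65
  CVZ:brain:
  - -18.6
  - -23.1
  - -16.6
  - -22.6
  - -12.6
  - -20.6
  CVZ:kidney:
  - -20.7
  - -25.2
  - -18.7
  - -24.7
  - -14.7
  - -22.7
  CVZ:liver:
  - -21.75
  - -26.25
  - -19.75
  - -25.75
  - -15.75
  - -23.75
  CVZ:muscle:
  - -19.65
  - -24.15
  - -17.65
  - -23.65
  - -13.65
  - -21.65
  DIET:none:
  - -23.5
  - -28.0
  - -21.5
  - -27.5
  - -17.5
  - -25.5
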