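# Default material definitions: calibration-phantom inserts and marrow
# surrogates.  Soft-tissue inserts follow ICRU 44 tissue compositions; bone
# inserts are hydroxyapatite at the vendor-nominal concentration in a
# water-equivalent base.  Override any entry via your own config file.
adipose:
  mass_fractions:
    H: 0.114
    C: 0.598
    N: 0.007
    O: 0.278
    Na: 0.001
    S: 0.001
    Cl: 0.001
  density_g_cm3: 0.96
breast:
  mass_fractions:
    H: 0.106
    C: 0.332
    N: 0.03
    O: 0.527
    Na: 0.001
    P: 0.001
    S: 0.002
    Cl: 0.001
  density_g_cm3: 0.99
muscle:
  mass_fractions:
    H: 0.102
    C: 0.143
    N: 0.034
    O: 0.71
    Na: 0.001
    P: 0.002
    S: 0.003
    Cl: 0.001
    K: 0.004
  density_g_cm3: 1.06
liver:
  mass_fractions:
    H: 0.102
    C: 0.139
    N: 0.03
    O: 0.716
    Na: 0.002
    P: 0.003
    S: 0.003
    Cl: 0.002
    K: 0.003
  density_g_cm3: 1.07
bone_200:
  mass_fractions:
    Ca: 0.068782
    P: 0.031894
    O: 0.806372
    H: 0.092951
  density_g_cm3: 1.16
bone_800:
  mass_fractions:
    Ca: 0.208594
    P: 0.096725
    O: 0.640242
    H: 0.054439
  density_g_cm3: 1.53
bone_1250:
  mass_fractions:
    Ca: 0.273994
    P: 0.127052
    O: 0.562531
    H: 0.036423
  density_g_cm3: 1.82
hydroxyapatite:
  mass_fractions:
    Ca: 0.398936
    P: 0.184987
    O: 0.41407
    H: 0.002007
  density_g_cm3: 3.0
peanut_oil:
  mass_fractions:
    C: 0.773193
    H: 0.118389
    O: 0.108418
  density_g_cm3: 0.915
water_phema:
  mass_fractions:
    H: 0.094674
    O: 0.628458
    C: 0.276868
  density_g_cm3: 1.069767441860465
water:
  mass_fractions:
    H: 0.111898
    O: 0.888102
  density_g_cm3: 1.0
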