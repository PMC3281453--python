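comment: N-acetylglucosamine-like monomer template, relaxed with the builtin minimal
  parameter set (synthetic geometry; not an experimental structure)
atoms:
- - C
  - 1.20475
  - -0.12033
  - 0.40276
  - 0.3
- - C
  - 0.52754
  - 1.07722
  - -0.29664
  - 0.1
- - C
  - -0.90803
  - 1.03083
  - 0.22388
  - 0.1
- - C
  - -1.55765
  - -0.15563
  - -0.48368
  - 0.1
- - C
  - -0.82737
  - -1.44364
  - 0.00568
  - 0.1
- - O
  - 0.61414
  - -1.35824
  - -0.00194
  - -0.3
- - O
  - 2.56821
  - -0.18795
  - 0.03603
  - -0.4
- - H
  - 3.05487
  - -0.21165
  - 0.86361
  - 0.3
- - N
  - 1.06458
  - 2.43563
  - -0.04196
  - -0.4
- - H
  - 1.30418
  - 2.92026
  - -0.89465
  - 0.3
- - C
  - 2.15557
  - 2.54097
  - 0.93518
  - 0.45
- - O
  - 2.94428
  - 3.6606
  - 0.60317
  - -0.45
- - C
  - 1.60421
  - 2.62996
  - 2.36191
  - 0.0
- - O
  - -1.61504
  - 2.25165
  - 0.06293
  - -0.4
- - H
  - -1.84787
  - 2.53422
  - 0.95014
  - 0.3
- - O
  - -2.96203
  - -0.10832
  - -0.27341
  - -0.4
- - H
  - -3.24575
  - -1.00593
  - -0.08816
  - 0.3
- - C
  - -1.29327
  - -1.95398
  - 1.39083
  - 0.1
- - O
  - -1.86058
  - -3.2454
  - 1.29646
  - -0.4
- - H
  - -2.68461
  - -3.2032
  - 1.78821
  - 0.3
- - H
  - 1.1203
  - -0.03636
  - 1.48855
  - 0.0
- - H
  - 0.54526
  - 0.86314
  - -1.36691
  - 0.0
- - H
  - -0.8737
  - 0.77495
  - 1.28501
  - 0.0
- - H
  - -1.3952
  - -0.08977
  - -1.56092
  - 0.0
- - H
  - -1.0501
  - -2.20255
  - -0.74504
  - 0.0
- - H
  - -2.01425
  - -1.26428
  - 1.83357
  - 0.0
- - H
  - -0.43581
  - -2.00653
  - 2.06259
  - 0.0
- - H
  - 0.51716
  - 2.5383
  - 2.35375
  - 0.0
- - H
  - 2.0153
  - 1.8016
  - 2.9398
  - 0.0
- - H
  - 1.88298
  - 3.57212
  - 2.83129
  - 0.0
bonds:
- - 0
  - 1
  - 1
- - 1
  - 2
  - 1
- - 2
  - 3
  - 1
- - 3
  - 4
  - 1
- - 4
  - 5
  - 1
- - 5
  - 0
  - 1
- - 0
  - 6
  - 1
- - 6
  - 7
  - 1
- - 1
  - 8
  - 1
- - 8
  - 9
  - 1
- - 8
  - 10
  - 1
- - 10
  - 11
  - 2
- - 10
  - 12
  - 1
- - 2
  - 13
  - 1
- - 13
  - 14
  - 1
- - 3
  - 15
  - 1
- - 15
  - 16
  - 1
- - 4
  - 17
  - 1
- - 17
  - 18
  - 1
- - 18
  - 19
  - 1
- - 0
  - 20
  - 1
- - 1
  - 21
  - 1
- - 2
  - 22
  - 1
- - 3
  - 23
  - 1
- - 4
  - 24
  - 1
- - 17
  - 25
  - 1
- - 17
  - 26
  - 1
- - 12
  - 27
  - 1
- - 12
  - 28
  - 1
- - 12
  - 29
  - 1
linkage:
  c1: 0
  o4: 15
  o1: 6
  drop_from_reducing:
  - 6
  - 7
  drop_from_nonreducing: 16
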