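# Default pairwise interaction-propensity matrix for the
# pairwise_energy predictor.  Additive form built from a signed
# per-residue disorder-propensity scale (TOP-IDP-like):
#   matrix[a][b] = (p(a) + p(b)) / 2
# so the estimated energy of a residue is the mean of its own
# propensity and its context's mean propensity.  Positive energy
# is disorder-prone; the logistic midpoint sits at 0 because the
# scale is signed around the order/disorder boundary.
window: 21
midpoint: 0.0
slope: 0.1
matrix:
  A:
    A: 0.0600
    C: 0.0400
    D: 0.1260
    E: 0.3980
    F: -0.3185
    G: 0.1130
    H: 0.1815
    I: -0.2130
    K: 0.3230
    L: -0.1330
    M: -0.1685
    N: 0.0335
    P: 0.5235
    Q: 0.1890
    R: 0.1200
    S: 0.2005
    T: 0.0595
    V: -0.0305
    W: -0.4120
    Y: -0.2250
  C:
    A: 0.0400
    C: 0.0200
    D: 0.1060
    E: 0.3780
    F: -0.3385
    G: 0.0930
    H: 0.1615
    I: -0.2330
    K: 0.3030
    L: -0.1530
    M: -0.1885
    N: 0.0135
    P: 0.5035
    Q: 0.1690
    R: 0.1000
    S: 0.1805
    T: 0.0395
    V: -0.0505
    W: -0.4320
    Y: -0.2450
  D:
    A: 0.1260
    C: 0.1060
    D: 0.1920
    E: 0.4640
    F: -0.2525
    G: 0.1790
    H: 0.2475
    I: -0.1470
    K: 0.3890
    L: -0.0670
    M: -0.1025
    N: 0.0995
    P: 0.5895
    Q: 0.2550
    R: 0.1860
    S: 0.2665
    T: 0.1255
    V: 0.0355
    W: -0.3460
    Y: -0.1590
  E:
    A: 0.3980
    C: 0.3780
    D: 0.4640
    E: 0.7360
    F: 0.0195
    G: 0.4510
    H: 0.5195
    I: 0.1250
    K: 0.6610
    L: 0.2050
    M: 0.1695
    N: 0.3715
    P: 0.8615
    Q: 0.5270
    R: 0.4580
    S: 0.5385
    T: 0.3975
    V: 0.3075
    W: -0.0740
    Y: 0.1130
  F:
    A: -0.3185
    C: -0.3385
    D: -0.2525
    E: 0.0195
    F: -0.6970
    G: -0.2655
    H: -0.1970
    I: -0.5915
    K: -0.0555
    L: -0.5115
    M: -0.5470
    N: -0.3450
    P: 0.1450
    Q: -0.1895
    R: -0.2585
    S: -0.1780
    T: -0.3190
    V: -0.4090
    W: -0.7905
    Y: -0.6035
  G:
    A: 0.1130
    C: 0.0930
    D: 0.1790
    E: 0.4510
    F: -0.2655
    G: 0.1660
    H: 0.2345
    I: -0.1600
    K: 0.3760
    L: -0.0800
    M: -0.1155
    N: 0.0865
    P: 0.5765
    Q: 0.2420
    R: 0.1730
    S: 0.2535
    T: 0.1125
    V: 0.0225
    W: -0.3590
    Y: -0.1720
  H:
    A: 0.1815
    C: 0.1615
    D: 0.2475
    E: 0.5195
    F: -0.1970
    G: 0.2345
    H: 0.3030
    I: -0.0915
    K: 0.4445
    L: -0.0115
    M: -0.0470
    N: 0.1550
    P: 0.6450
    Q: 0.3105
    R: 0.2415
    S: 0.3220
    T: 0.1810
    V: 0.0910
    W: -0.2905
    Y: -0.1035
  I:
    A: -0.2130
    C: -0.2330
    D: -0.1470
    E: 0.1250
    F: -0.5915
    G: -0.1600
    H: -0.0915
    I: -0.4860
    K: 0.0500
    L: -0.4060
    M: -0.4415
    N: -0.2395
    P: 0.2505
    Q: -0.0840
    R: -0.1530
    S: -0.0725
    T: -0.2135
    V: -0.3035
    W: -0.6850
    Y: -0.4980
  K:
    A: 0.3230
    C: 0.3030
    D: 0.3890
    E: 0.6610
    F: -0.0555
    G: 0.3760
    H: 0.4445
    I: 0.0500
    K: 0.5860
    L: 0.1300
    M: 0.0945
    N: 0.2965
    P: 0.7865
    Q: 0.4520
    R: 0.3830
    S: 0.4635
    T: 0.3225
    V: 0.2325
    W: -0.1490
    Y: 0.0380
  L:
    A: -0.1330
    C: -0.1530
    D: -0.0670
    E: 0.2050
    F: -0.5115
    G: -0.0800
    H: -0.0115
    I: -0.4060
    K: 0.1300
    L: -0.3260
    M: -0.3615
    N: -0.1595
    P: 0.3305
    Q: -0.0040
    R: -0.0730
    S: 0.0075
    T: -0.1335
    V: -0.2235
    W: -0.6050
    Y: -0.4180
  M:
    A: -0.1685
    C: -0.1885
    D: -0.1025
    E: 0.1695
    F: -0.5470
    G: -0.1155
    H: -0.0470
    I: -0.4415
    K: 0.0945
    L: -0.3615
    M: -0.3970
    N: -0.1950
    P: 0.2950
    Q: -0.0395
    R: -0.1085
    S: -0.0280
    T: -0.1690
    V: -0.2590
    W: -0.6405
    Y: -0.4535
  N:
    A: 0.0335
    C: 0.0135
    D: 0.0995
    E: 0.3715
    F: -0.3450
    G: 0.0865
    H: 0.1550
    I: -0.2395
    K: 0.2965
    L: -0.1595
    M: -0.1950
    N: 0.0070
    P: 0.4970
    Q: 0.1625
    R: 0.0935
    S: 0.1740
    T: 0.0330
    V: -0.0570
    W: -0.4385
    Y: -0.2515
  P:
    A: 0.5235
    C: 0.5035
    D: 0.5895
    E: 0.8615
    F: 0.1450
    G: 0.5765
    H: 0.6450
    I: 0.2505
    K: 0.7865
    L: 0.3305
    M: 0.2950
    N: 0.4970
    P: 0.9870
    Q: 0.6525
    R: 0.5835
    S: 0.6640
    T: 0.5230
    V: 0.4330
    W: 0.0515
    Y: 0.2385
  Q:
    A: 0.1890
    C: 0.1690
    D: 0.2550
    E: 0.5270
    F: -0.1895
    G: 0.2420
    H: 0.3105
    I: -0.0840
    K: 0.4520
    L: -0.0040
    M: -0.0395
    N: 0.1625
    P: 0.6525
    Q: 0.3180
    R: 0.2490
    S: 0.3295
    T: 0.1885
    V: 0.0985
    W: -0.2830
    Y: -0.0960
  R:
    A: 0.1200
    C: 0.1000
    D: 0.1860
    E: 0.4580
    F: -0.2585
    G: 0.1730
    H: 0.2415
    I: -0.1530
    K: 0.3830
    L: -0.0730
    M: -0.1085
    N: 0.0935
    P: 0.5835
    Q: 0.2490
    R: 0.1800
    S: 0.2605
    T: 0.1195
    V: 0.0295
    W: -0.3520
    Y: -0.1650
  S:
    A: 0.2005
    C: 0.1805
    D: 0.2665
    E: 0.5385
    F: -0.1780
    G: 0.2535
    H: 0.3220
    I: -0.0725
    K: 0.4635
    L: 0.0075
    M: -0.0280
    N: 0.1740
    P: 0.6640
    Q: 0.3295
    R: 0.2605
    S: 0.3410
    T: 0.2000
    V: 0.1100
    W: -0.2715
    Y: -0.0845
  T:
    A: 0.0595
    C: 0.0395
    D: 0.1255
    E: 0.3975
    F: -0.3190
    G: 0.1125
    H: 0.1810
    I: -0.2135
    K: 0.3225
    L: -0.1335
    M: -0.1690
    N: 0.0330
    P: 0.5230
    Q: 0.1885
    R: 0.1195
    S: 0.2000
    T: 0.0590
    V: -0.0310
    W: -0.4125
    Y: -0.2255
  V:
    A: -0.0305
    C: -0.0505
    D: 0.0355
    E: 0.3075
    F: -0.4090
    G: 0.0225
    H: 0.0910
    I: -0.3035
    K: 0.2325
    L: -0.2235
    M: -0.2590
    N: -0.0570
    P: 0.4330
    Q: 0.0985
    R: 0.0295
    S: 0.1100
    T: -0.0310
    V: -0.1210
    W: -0.5025
    Y: -0.3155
  W:
    A: -0.4120
    C: -0.4320
    D: -0.3460
    E: -0.0740
    F: -0.7905
    G: -0.3590
    H: -0.2905
    I: -0.6850
    K: -0.1490
    L: -0.6050
    M: -0.6405
    N: -0.4385
    P: 0.0515
    Q: -0.2830
    R: -0.3520
    S: -0.2715
    T: -0.4125
    V: -0.5025
    W: -0.8840
    Y: -0.6970
  Y:
    A: -0.2250
    C: -0.2450
    D: -0.1590
    E: 0.1130
    F: -0.6035
    G: -0.1720
    H: -0.1035
    I: -0.4980
    K: 0.0380
    L: -0.4180
    M: -0.4535
    N: -0.2515
    P: 0.2385
    Q: -0.0960
    R: -0.1650
    S: -0.0845
    T: -0.2255
    V: -0.3155
    W: -0.6970
    Y: -0.5100
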