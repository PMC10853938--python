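# Electronegativity-equalization parameters, per element and coordination
# number.  A = intrinsic electronegativity, B = hardness (as-tabulated units).
# CN column: single value, comma list, dash range, or * (any CN).
# element  cn      A       B
H    1     2.364   0.961
H    2     2.304   1.458
C    1,2   2.452   0.658
C    3     2.435   0.658
C    4     2.422   0.672
N    1     2.628   0.872
N    2     2.534   0.679
N    3     2.502   0.634
N    4     2.824   1.551
O    1     2.545   0.720
O    2,3   2.502   0.675
F    *     2.577   1.478
Si   3     2.300   0.600
Si   4     2.300   0.605
P    1-3   2.448   0.705
P    4     2.444   0.436
P    5     2.624   0.465
S    1     2.501   0.562
S    2     2.461   0.961
S    3     2.382   0.556
S    4     2.304   0.789
S    5     2.226   0.675
S    6     2.941   0.601
Cl   *     2.446   0.644
Br   *     2.420   0.412
I    *     2.426   0.746
# global screening lengths, Angstrom
kappa   0.991
kappa2  1.371
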