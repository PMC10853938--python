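# Solvent registry: name; dielectric constant; boiling point (C);
# heavy (non-hydrogen) atoms per solvent molecule.
# Values are standard handbook constants at ~25 C. User-editable; extra
# entries may be appended in the same format.
# name                  epsilon   bp      heavy_atoms
water                   78.36     100.0   1
methanol                32.61     64.7    2
ethanol                 24.85     78.2    3
propanol                20.52     97.2    4
isopropanol             19.26     82.3    4
butanol                 17.33     117.7   5
isobutanol              16.78     107.9   5
sec-butanol             15.94     99.5    5
pentanol                15.13     137.9   6
hexanol                 12.51     157.6   7
heptanol                11.32     176.4   8
octanol                 9.86      195.2   9
nonanol                 8.60      213.1   10
decanol                 7.53      231.1   11
benzyl alcohol          12.46     205.3   8
m-cresol                12.44     202.2   8
methoxyethanol          17.20     124.1   5
dimethyl sulfoxide      46.83     189.0   4
acetonitrile            35.69     81.6    3
dimethylformamide       37.22     153.0   5
dimethylacetamide       37.78     165.1   6
methyl formamide        181.56    199.5   3
nitromethane            36.56     101.2   4
nitroethane             28.29     114.0   5
nitrobenzene            34.81     210.8   10
benzonitrile            25.59     191.1   9
acetophenone            17.44     202.0   9
butanone                18.25     79.6    4
cyclohexanone           15.62     155.4   7
4-methyl-2-pentanone    12.89     116.5   7
pyridine                12.98     115.3   6
2-methylpyridine        9.95      129.4   7
sulfolane               43.26     287.3   6
dichloroethane          10.13     83.5    4
o-dichlorobenzene       9.99      180.5   8
bromoethane             9.01      38.4    3
pentane                 1.84      36.1    5
hexane                  1.88      68.7    6
heptane                 1.92      98.4    7
octane                  1.94      125.6   8
nonane                  1.96      150.8   9
decane                  1.98      174.1   10
hexadecane              2.04      286.9   16
cyclohexane             2.02      80.7    6
benzene                 2.27      80.1    6
toluene                 2.38      110.6   7
xylene                  2.27      138.4   8
mesitylene              2.27      164.7   9
tetralin                2.77      207.6   10
decalin                 2.20      195.8   10
perfluorobenzene        2.03      80.3    12
chloroform              4.71      61.2    5
carbon tetrachloride    2.23      76.7    5
methylene chloride      8.93      39.6    3
bromoform               4.25      149.1   4
tetrachloroethene       2.27      121.3   6
diethyl ether           4.24      34.5    5
dibutyl ether           3.05      140.2   9
tetrahydrofuran         7.43      66.0    5
anisole                 4.22      153.7   8
ethyl acetate           5.99      77.1    6
butyl acetate           4.94      126.1   8
acetic acid             6.25      117.9   4
aniline                 6.89      184.1   7
triethylamine           2.38      88.9    7
carbon disulfide        2.61      46.2    3
chlorobenzene           5.70      131.7   7
bromobenzene            5.40      156.0   7
iodobenzene             4.55      188.3   7
fluorobenzene           5.42      84.7    7
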