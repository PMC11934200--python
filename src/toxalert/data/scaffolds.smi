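c1ccccc1 benzene
Cc1ccccc1 toluene
CCc1ccccc1 ethylbenzene
COc1ccccc1 anisole
Oc1ccccc1 phenol
c1ccc2ccccc2c1 naphthalene
Cc1ccc(C)cc1 p-xylene
c1ccc(-c2ccccc2)cc1 biphenyl
C1CCCCC1 cyclohexane
CC1CCCCC1 methylcyclohexane
C1CCCC1 cyclopentane
C1CCCCCC1 cycloheptane
C1CCC2CCCCC2C1 decalin
c1ccc2c(c1)CCCC2 tetralin
c1ccc2c(c1)CCC2 indane
c1ccc2c(c1)CCO2 dihydrobenzofuran
c1ccc2c(c1)CCCO2 chroman
c1ccc2occc2c1 benzofuran
C1CCOCC1 oxane
C1CCOC1 oxolane
C1COCCO1 dioxane
CC(C)c1ccccc1 cumene
CC(C)(C)c1ccccc1 tert-butylbenzene
COc1ccc(C)cc1 methylanisole
Oc1ccc(C)cc1 cresol
CCCCCC hexane
CC(C)CC(C)C dimethylpentane-like
CCOc1ccccc1 phenetole
c1ccc(Cc2ccccc2)cc1 diphenylmethane
CC1(C)CCCCC1 gem-dimethylcyclohexane
C1CC2CCC1CC2 bicyclooctane
c1ccc(OCC2CC2)cc1 cyclopropylmethoxybenzene
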