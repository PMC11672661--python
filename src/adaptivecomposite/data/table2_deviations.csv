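molecule,dhf_exp_kcal,deviation_kcal
SiF4,-386.0,0.35
CH2CO,-11.4,-0.67
PF5,-381.1,2.42
CH3CH2NH2,-11.3,0.51
C2F6,-321.3,2.59
cycC5H10NH,-11.3,-0.21
Al2Cl6,-309.7,0.44
C2H5SH-ethanethiol,-11.1,0.35
SF6,-291.7,2.27
NH3,-11,-0.45
AlF3,-289.0,-0.65
CBrCl3,-10,-1.89
BF3,-271.4,2.05
CH3SCH3,-8.9,0.58
PF3,-229.1,0.11
C4H4O,-8.3,1.89
C6F6,-228.4,2.56
C4H8S,-8.2,-1.31
CF4,-223.0,1.98
CH3SiH3,-7,0.50
C6F5Cl,-194.1,-2.09
(CH3)3N,-5.7,0.56
BeF2,-190.3,-0.03
CH3SH,-5.5,0.79
CF3Cl,-169.5,2.08
CH3NH2,-5.5,-0.62
CHF3,-166.6,1.01
ClFO3,-5.1,0.08
SiCl4,-158.0,-2.15
H2S,-4.9,0.64
C2F4,-157.4,3.69
(CH3)2NH,-4.4,-0.43
CF3Br,-155.0,1.63
SCl2,-4.2,-0.98
COF2,-149.1,-4.23
H2COH,-4.1,0.19
AlCl3,-139.7,-0.36
"C4H8,isobutane",-4.0,-0.04
CH3-C=OOC=OCH3,-136.8,0.85
S2Cl2,-4.0,-0.16
POCl3,-133.8,9.95
CH3CH2O,-3.7,1.00
CF3CN,-118.4,-1.58
C4H6O,-3.3,-0.98
"CH3C=OOCH(CH3)2, isopropylacetate",-115.1,-0.25
C2Cl4,-3.0,0.37
CF3,-111.3,1.25
CH3CO (2A),-2.4,-0.22
CH2F2,-107.7,0.23
C4H8NH,-0.8,0.28
CH3COF,-105.7,1.00
F2,0.0,0.80
CH3COOH,-103.4,0.40
H2,0.0,0.71
CHF2Br,-101.6,0.12
Cl2,0.0,0.50
CH3COOCH3,-98.4,0.28
O2,0.0,0.31
BCl3,-96.3,-1.01
N2,0.0,-0.35
SO3,-94.6,-0.17
SO,1.2,-0.80
CO2,-94.1,0.70
PH3,1.3,-0.38
MgCl2,-93.8,-0.33
N2O4,2.2,-0.31
CH3-CH(OCH3)2,-93.1,2.63
ClNO2,2.9,0.80
HCOOH,-90.5,1.37
CH3O,4.1,-0.01
(CH3)2SO2,-89.7,-1.36
CH3-CH=CH2,4.8,0.11
PCl5,-86.1,1.53
(CH3)2CHCN,5.6,-0.66
HCOOCH3,-85.0,2.48
F2O,5.9,2.10
SO2Cl2,-84.8,6.63
"C4H8,cyclobutane",6.8,0.77
LiF,-80.1,-1.18
NO2,7.9,-0.45
(CH3)2CHOCH(CH3)2,-76.3,-0.02
SiH4,8.2,1.16
"C4H8O2,(para)",-75.5,1.40
CH2=CHCl,8.9,1.75
(CH3)3COH,-74.7,0.26
OH,9.4,0.99
"C6H4F2, 1,3-difluorobenzene",-73.9,-1.40
HCO,10.0,-1.02
"C6H4F2, 1,4-difluorobenzene",-73.3,-1.43
"C6H5-CH3,toluene",12.0,-1.01
SO2,-71.0,0.67
(CH3)3C,12.3,-0.08
NaF,-69.4,-2.11
C6H5Cl,12.4,3.12
PCl3,-69.0,-1.85
ClNO,12.4,-0.15
(CH3)3COCH3,-67.8,0.38
C2H4,12.5,-0.06
(CH3)2CHOH,-65.2,0.76
"C3H6,cyclopropane",12.7,-0.24
HF,-65.1,0.71
P4,14.1,-1.33
AlF,-63.5,0.25
CH3C=OCCH,15.6,-0.96
CH3CH2COCH2CH3,-61.6,-0.85
"C5H8,isoprene",18.0,-0.46
CH3CH2OCH2CH3,-60.3,0.54
CH3CN,18.0,0.56
CH3COCl,-58.0,-0.49
C2H3Br,18.9,-1.55
H2O,-57.8,0.11
Si2H6,19.1,1.79
"CH3COCH2CH3, methylethylketone",-57.1,-0.47
N2O,19.6,-0.53
CH3CONH2,-57.0,0.08
C2H4S,19.6,0.41
CH3CH2OH,-56.2,1.04
C6H6,19.7,-1.13
Si(CH3)4,-55.7,-3.97
N2O3,19.8,-0.16
C5H10O,-53.4,-1.11
"C5H6S,methylthiophene,",20.0,-2.59
Cl2CO,-52.4,-0.73
C4H6S,20.8,-0.79
CH3COCH3,-51.9,-0.34
C6H5NH2,20.8,-1.35
C2H5OCH3methyl-ethyl-ether,-51.7,1.50
(CH3)2CH,21.5,0.76
"(CH3)2CHCHO,isobutanal",-51.6,-1.82
NO,21.6,-0.91
HCOCOH,-50.7,2.48
H2NNH2,22.8,-0.90
C8H18,-49.9,1.45
ClO,24.2,-0.91
H3COH,-48.0,1.51
C5H7N,24.6,-0.91
C5H8O,-45.9,-1.47
"C6H8,1,4-cyclohexadiene",25.0,-0.80
C7H16,-44.9,1.30
C6H5Br,25.2,-2.97
CH3OCH3,-44.0,1.52
"C6H8,1,3-cyclohexadiene",25.4,-0.44
C4H8O (tetrahydrofuran),-44.0,-0.76
C4H5N,25.9,-1.07
NaCl,-43.8,-1.58
"CH2CHCHCH2,butadiene",26.3,-0.59
(CH3)3CCl,-43.5,1.38
C4H4S,27.5,-1.52
"C6H14,methylpentane",-41.1,0.54
CS2,28.0,-1.09
SiCl2,-40.3,-2.43
C2H5,28.9,0.67
"C5H12,neopentane",-40.2,-0.08
CH3S,29.8,0.96
C6H14,-39.9,1.18
C2H4NH,30.2,-0.10
CH3CHO,-39.7,0.23
S2,30.7,-1.30
"CH3CH2CH(CH3)NO2, nitro-s-butane",-39.1,0.86
HCN,31.5,0.43
ClF3,-38.0,-19.68
ClCN,32.9,-0.83
CH3CH2CH2CH2Cl,-37.0,0.72
PH2,33.1,1.00
(CH3)2SO,-36.2,0.08
LiH,33.3,0.37
C6H13Br,-35.4,-1.33
C5H5N,33.6,-0.51
"C5H12,n-pentane",-35.1,0.77
Na2,34.0,0.26
CH2=CHF,-33.2,0.40
O3,34.1,0.92
OCS,-33.0,0.64
HS,34.2,0.45
H2O2,-32.5,2.01
P2,34.3,-1.02
"C4H10,ISO",-32.1,0.37
"C4H6,2-butyne",34.8,-0.18
NF3,-31.6,0.02
CH3,35.0,0.35
CH3CH2CH2Cl,-31.5,1.99
"C10H8,naphthalene",35.9,-0.89
"C4H10,trans",-30.0,0.75
"C4H6,cyclobutene",37.4,-0.92
C6H12,-29.5,0.38
CH3-CH=C=CH2,38.8,0.36
C6H4O2,-29.4,-3.49
CH2CHCN,43.2,-1.47
"(CH3)3CNH2,t-butylamine",-28.9,0.13
LiNa,43.4,0.33
C6H5F,-27.7,4.53
CH3CCH,44.2,0.27
COBr2,-27.1,-3.29
"C5H8,spiropentane",44.3,0.02
C2H5Cl,-26.8,1.43
NH2,45.1,1.43
CO,-26.4,-0.47
"CH2=C=CH2, (allene)",45.5,0.50
(CH3)3CSH,-26.2,0.49
"C4H4N2,1,4-dipyridine",46.8,-3.08
H2CO,-26.0,0.46
"C4H4N2,pyrimidine",46.9,1.48
"C3H8,propene",-25.0,0.56
SiH3,47.9,0.99
CHCl3,-24.7,-0.94
C4H6-methylenecyclopropane,47.9,1.90
SiO,-24.6,-1.20
NCCH2CH2CN,50.1,0.68
CH3CH=CHCHO,-24.0,-0.39
Li2,51.6,0.27
C3H7Br,-23.8,-2.35
"C4H6,bicyclo",51.9,-1.67
C6H5OH,-23.0,-1.01
C2H2,54.2,-0.28
CCl4,-22.9,-1.06
"SiH2,singlete",65.2,1.33
CH2Cl2,-22.8,-0.58
C3H4,66.2,-1.30
HCl,-22.1,0.80
CS,66.9,-0.69
C2H6,-20.1,0.38
"C10H8,azulene",69.1,-2.92
CH3Cl,-19.5,-0.13
C8H8,70.7,-1.18
"C5H10,cyclopentane",-18.3,0.17
C2H3,71.6,0.40
CH3CH2SSCH2CH3,-17.9,-1.21
NCCN,73.3,-0.46
CH4,-17.9,0.03
"C6H5, phenilradical",81.2,-2.87
CH3NO2,-17.8,-1.10
BeH,81.7,-0.42
HOCl,-17.8,1.13
NH,85.2,0.77
C3H6Br2,-17.1,-0.24
"SiH2,triplet",86.2,1.00
CH3ONO,-15.9,0.30
"CH2,triplet",93.7,-0.15
C5H10S,-15.2,-1.55
"CH2,singlet",102.8,0.46
C2H5Br,-14.8,-0.94
CN,104.9,-2.21
ClF,-13.2,0.39
CCH,135.1,-1.14
C5H8Br2,-13.1,-0.32
Si2,139.9,-1.15
C2H4O,-12.6,0.94
CH,142.5,0.43
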