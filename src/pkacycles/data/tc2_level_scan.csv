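level_of_theory,solvent_model,calculated_pka,delta_printed
B3LYP/6-31+G*,CPCM,8.17,-3.00
B3LYP/6-31+G**,CPCM,7.65,-4.05
B3LYP/6-31G**,CPCM,7.55,-4.15
B3LYP/6-31++G**,CPCM,5.69,-6.01
B3LYP/6-31++G**//B3LYP/6-31+G*,CPCM,7.20,-4.50
B3LYP/6-31++G**//B3LYP/6-31G**,CPCM,8.42,-3.28
B3LYP/6-31+G*,SMD,9.21,-2.49
B3LYP/6-31+G**,SMD,9.12,-2.58
B3LYP/6-31G**,SMD,9.08,-2.62
B3LYP/6-31++G**,SMD,8.05,-3.65
B3LYP/6-31++G**//B3LYP/6-31+G*,SMD,7.80,-2.90
B3LYP/6-31++G**//B3LYP/6-31G**,SMD,8.69,-3.01
wB97XD/6-31+G*,CPCM,5.64,-6.06
wB97XD/6-31+G**,CPCM,5.01,-6.69
wB97XD/6-31G**,CPCM,9.68,-2.02
wB97XD/6-31++G**,CPCM,7.90,-3.80
wB97XD/6-31++G**//wB97XD/6-31+G*,CPCM,6.50,-5.20
wB97XD/6-31++G**//wB97XD/6-31G**,CPCM,6.12,-5.58
wB97XD/6-31+G*,SMD,9.64,-2.06
wB97XD/6-31+G**,SMD,9.12,-2.58
wB97XD/6-31G**,SMD,8.55,-3.15
wB97XD/6-31++G**,SMD,9.05,-2.65
wB97XD/6-31++G**//wB97XD/6-31+G*,SMD,7.43,-4.27
wB97XD/6-31++G**//wB97XD/6-31G**,SMD,7.01,-4.69
M062X/6-31+G*,CPCM,9.68,-2.02
M062X/6-31+G**,CPCM,8.56,-3.14
M062X/6-31G**,CPCM,7.98,-3.02
M062X/6-31++G**,CPCM,9.02,-2.68
M062X/6-31++G**//M062X/6-31+G*,CPCM,9.13,-2.57
M062X/6-31++G**//M062X/6-31G**,CPCM,9.27,-2.43
M062X/6-31+G*,SMD,6.87,-4.83
M062X/6-31+G**,SMD,10.00,-1.70
M062X/6-31G**,SMD,12.47,0.77
M062X/6-31++G**,SMD,8.45,-3.25
M062X/6-31++G**//M062X/6-31+G*,SMD,8.70,-3.00
M062X/6-31++G**//M062X/6-31G**,SMD,7.32,-4.38
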