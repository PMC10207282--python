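level_of_theory,solvent_model,calculated_pka_1,delta_printed_1,calculated_pka_2,delta_printed_2
B3LYP/6-31+G*,CPCM,2.13,-9.57,0.27,-10.43
B3LYP/6-31+G**,CPCM,2.45,-9.25,0.59,-10.11
B3LYP/6-31G**,CPCM,7.68,-4.02,5.82,-5.88
B3LYP/6-31++G**,CPCM,3.65,-8.05,1.79,-9.91
B3LYP/6-31++G**//B3LYP/6-31+G*,CPCM,3.63,-8.07,1.77,-9.93
B3LYP/6-31++G**//B3LYP/6-31G**,CPCM,3.62,-8.08,1.76,-9.94
B3LYP/6-31+G*,SMD,6.55,-5.15,4.68,-7.02
B3LYP/6-31+G**,SMD,6.60,-5.10,4.74,-6.96
B3LYP/6-31G**,SMD,5.57,-5.13,3.83,-7.87
B3LYP/6-31++G**,SMD,6.67,-5.03,4.40,-7.30
B3LYP/6-31++G**//B3LYP/6-31+G*,SMD,6.02,-5.68,3.90,-7.80
B3LYP/6-31++G**//B3LYP/6-31G**,SMD,6.14,-5.56,4.48,-7.22
wB97XD/6-31+G*,CPCM,3.75,-7.95,1.89,-9.81
wB97XD/6-31+G**,CPCM,5.62,-6.08,4.70,-7.00
wB97XD/6-31G**,CPCM,8.49,-3.21,6.63,-5.07
wB97XD/6-31++G**,CPCM,5.15,-6.55,3.29,-8.41
wB97XD/6-31++G**//wB97XD/6-31+G*,CPCM,5.14,-6.56,3.28,-8.42
wB97XD/6-31++G**//wB97XD/6-31G**,CPCM,5.15,-6.55,2.29,-9.41
wB97XD/6-31+G*,SMD,7.59,-4.11,6.02,-5.68
wB97XD/6-31+G**,SMD,8.00,-3.70,6.14,-5.56
wB97XD/6-31G**,SMD,7.43,-4.27,5.49,-6.21
wB97XD/6-31++G**,SMD,8.45,-3.25,6.72,-4.98
wB97XD/6-31++G**//wB97XD/6-31+G*,SMD,6.43,-5.27,4.58,-7.12
wB97XD/6-31++G**//wB97XD/6-31G**,SMD,7.00,-4.70,5.92,-5.78
M062X/6-31+G*,CPCM,5.55,-6.15,4.68,-7.02
M062X/6-31+G**,CPCM,5.69,-6.01,4.23,-7.47
M062X/6-31G**,CPCM,8.01,-3.69,6.75,-4.95
M062X/6-31++G**,CPCM,5.59,-6.11,4.02,-7.68
M062X/6-31++G**//M062X/6-31+G*,CPCM,5.52,-6.18,3.69,-8.01
M062X/6-31++G**//M062X/6-31G**,CPCM,5.01,-6.69,3.53,-8.17
M062X/6-31+G*,SMD,4.59,-7.11,2.73,-8.97
M062X/6-31+G**,SMD,4.70,-7.00,2.84,-8.86
M062X/6-31G**,SMD,9.14,-2.56,7.28,-4.42
M062X/6-31++G**,SMD,6.04,-5.66,4.18,-7.52
M062X/6-31++G**//M062X/6-31+G*,SMD,6.01,-5.69,4.15,-7.55
M062X/6-31++G**//M062X/6-31G**,SMD,5.95,-5.75,4.09,-7.61
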