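molecule_id,experimental_pka_mecn,calculated_pka_mecn,delta_printed_mecn,experimental_pka_water,calculated_pka_water,delta_printed_water
1,24.77,24.13,-0.64,13.50,13.02,-0.48
2,19.83,20.60,0.77,,11.56,
3,19.36,19.43,0.07,,11.30,
4,18.11,17.74,-0.37,9.60,9.07,-0.53
5,17.78,17.40,-0.38,9.17,9.02,-0.15
6,16.44,16.70,0.26,9.34,9.06,-0.28
7,16.02,16.11,0.09,,8.76,
8,15.96,15.87,-0.09,,8.45,
9,14.32,15.03,-0.71,6.78,6.43,-0.35
10,15.08,14.77,-0.31,7.43,7.70,0.27
11,13.94,14.56,0.12,6.13,5.85,-0.28
12,13.88,14.26,0.38,6.82,6.60,-0.22
13,14.02,14.04,0.02,6.58,7.00,0.42
14,14.31,13.96,-0.35,6.04,5.64,-0.40
15,13.77,13.92,0.15,6.72,6.32,-0.40
16,12.98,13.11,0.13,5.81,5.19,-0.38
17,12.56,12.33,-0.23,5.23,5.43,0.20
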