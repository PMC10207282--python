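molecule_id,atom_index,element,scheme,charge,site_label
1RR,8,N,NPA,-0.582,imine-N
1RR,8,N,CM5,-0.616,imine-N
1RR,8,N,Hirshfeld,-0.602,imine-N
1RR,3,N,NPA,-0.336,ring-N
1RR,3,N,CM5,-0.445,ring-N
1RR,3,N,Hirshfeld,-0.403,ring-N
2RR,8,N,NPA,-0.594,imine-N
2RR,8,N,CM5,-0.626,imine-N
2RR,8,N,Hirshfeld,-0.612,imine-N
2RR,3,N,NPA,-0.345,ring-N
2RR,3,N,CM5,-0.455,ring-N
2RR,3,N,Hirshfeld,-0.413,ring-N
3RR,8,N,NPA,-0.612,imine-N
3RR,8,N,CM5,-0.647,imine-N
3RR,8,N,Hirshfeld,-0.625,imine-N
3RR,3,N,NPA,-0.409,ring-N
3RR,3,N,CM5,-0.489,ring-N
3RR,3,N,Hirshfeld,-0.447,ring-N
4RR,8,N,NPA,-0.623,imine-N
4RR,8,N,CM5,-0.659,imine-N
4RR,8,N,Hirshfeld,-0.646,imine-N
4RR,3,N,NPA,-0.421,ring-N
4RR,3,N,CM5,-0.435,ring-N
4RR,3,N,Hirshfeld,-0.428,ring-N
5RR,8,N,NPA,-0.745,imine-N
5RR,8,N,CM5,-0.802,imine-N
5RR,8,N,Hirshfeld,-0.767,imine-N
5RR,3,N,NPA,-0.471,ring-N
5RR,3,N,CM5,-0.455,ring-N
5RR,3,N,Hirshfeld,-0.463,ring-N
6RR,8,N,NPA,-0.704,imine-N
6RR,8,N,CM5,-0.759,imine-N
6RR,8,N,Hirshfeld,-0.738,imine-N
6RR,3,N,NPA,-0.436,ring-N
6RR,3,N,CM5,-0.448,ring-N
6RR,3,N,Hirshfeld,-0.442,ring-N
7RR,8,N,NPA,-0.824,imine-N
7RR,8,N,CM5,-0.865,imine-N
7RR,8,N,Hirshfeld,-0.847,imine-N
7RR,3,N,NPA,-0.503,ring-N
7RR,3,N,CM5,-0.532,ring-N
7RR,3,N,Hirshfeld,-0.517,ring-N
8RR,8,N,NPA,-0.805,imine-N
8RR,8,N,CM5,-0.849,imine-N
8RR,8,N,Hirshfeld,-0.836,imine-N
8RR,3,N,NPA,-0.487,ring-N
8RR,3,N,CM5,-0.545,ring-N
8RR,3,N,Hirshfeld,-0.503,ring-N
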