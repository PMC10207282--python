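molecule_id,atom_index,element,scheme,charge,site_label
2-imino-thiazolidinone,6,N,NPA,-0.628,2-imino-N
2-imino-thiazolidinone,3,N,NPA,-0.521,N3
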