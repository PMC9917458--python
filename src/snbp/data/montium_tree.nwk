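((((D_kikkawai:1,D_bocqueti:1):1,(D_jambulina:1,D_chauvacae:1):1):1,((D_triauraria:1,D_fuyamai:1):1,(D_serrata:1,(D_bunnanda:1,D_birchii:1):1):1):1):1,(D_truncata:1,D_mayri:1):1);
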