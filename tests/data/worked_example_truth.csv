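spectrum_ordinal,truth_class,ligand,true_delta_mass,implanted_reporters,n_implanted_reporters,true_charge,rt
0,adduct,pyridoxal,151.06332853263,y1;y2;y3;y4;y5;y6;y7;y8;y9;y10;y11;y12,12,3,1878.4094113524409
1,adduct,pyridoxal,151.06332853263,y1;y2;y3;y4;y5;y6;y7;y8;y9;y10;y11;y12,12,3,2318.627638623525
2,adduct,glyoxal,42.01056468374,y1;y2;y3;y4;y5;y6;y7;y8;y9;y10;y11;y12,12,3,2356.8593800430413
3,unmodified,,0.0,y1;y2;y3;y4;y5;y6;y7;y8;y9;y10;y11;y12,12,3,1903.631884458769
4,decoy,,682.9850056524288,,0,3,2307.2817638106253
5,decoy,,-203.35131346017397,,0,3,1755.9801021309818
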