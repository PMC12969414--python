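spectrum_ordinal,scan_title,rt_seconds,precursor_mz,assumed_charge,Delta_Mass,y1,y2,y3,y4,y5,y6,y7,y8,y9,y10,y11,y12,#Fragments,Delta_Mass_Oxygen,passes_filters,stringent
0,adduct:pyridoxal:0,1878.4094113524409,574.2970321710844,3,151.06332853263007,1,1,1,1,1,1,1,1,1,1,1,1,12,167.05824315223006,1,1
1,adduct:pyridoxal:1,2318.627638623525,574.2970321710844,3,151.06332853263007,1,1,1,1,1,1,1,1,1,1,1,1,12,167.05824315223006,1,1
2,adduct:glyoxal:0,2356.8593800430413,537.9461108881211,3,42.01056468374031,1,1,1,1,1,1,1,1,1,1,1,1,12,58.00547930334031,1,1
3,unmodified:0,1903.631884458769,523.9425893268743,3,-2.2737367544323206e-13,1,1,1,1,1,1,1,1,1,1,1,1,12,15.994914619599772,0,1
4,decoy:0,2307.2817638106253,751.6042578776838,3,682.9850056524288,0,0,0,0,0,0,0,0,0,0,0,0,0,698.9799202720287,0,0
5,decoy:1,1755.9801021309818,456.15881817348304,3,-203.35131346017397,0,0,0,0,0,0,0,0,0,0,0,0,0,-187.35639884057397,0,0
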