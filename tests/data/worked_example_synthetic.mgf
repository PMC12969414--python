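BEGIN IONS
TITLE=adduct:pyridoxal:0
PEPMASS=574.297032
CHARGE=3+
RTINSECONDS=1878.4094
205.097154 1000
302.149918 1000
373.187032 1000
529.288143 1000
626.340907 1000
755.383500 1000
1034.541791 1000
1162.600369 1000
1318.701480 1000
1419.749158 1000
1518.817572 1000
1605.849601 1000
END IONS
BEGIN IONS
TITLE=adduct:pyridoxal:1
PEPMASS=574.297032
CHARGE=3+
RTINSECONDS=2318.6276
205.097154 1000
302.149918 1000
373.187032 1000
529.288143 1000
626.340907 1000
755.383500 1000
1034.541791 1000
1162.600369 1000
1318.701480 1000
1419.749158 1000
1518.817572 1000
1605.849601 1000
END IONS
BEGIN IONS
TITLE=adduct:glyoxal:0
PEPMASS=537.946111
CHARGE=3+
RTINSECONDS=2356.8594
205.097154 1000
302.149918 1000
373.187032 1000
529.288143 1000
626.340907 1000
755.383500 1000
925.489027 1000
1053.547605 1000
1209.648716 1000
1310.696394 1000
1409.764808 1000
1496.796837 1000
END IONS
BEGIN IONS
TITLE=unmodified:0
PEPMASS=523.942589
CHARGE=3+
RTINSECONDS=1903.6319
205.097154 1000
302.149918 1000
373.187032 1000
529.288143 1000
626.340907 1000
755.383500 1000
883.478463 1000
1011.537040 1000
1167.638151 1000
1268.685830 1000
1367.754244 1000
1454.786272 1000
END IONS
BEGIN IONS
TITLE=decoy:0
PEPMASS=751.604258
CHARGE=3+
RTINSECONDS=2307.2818
END IONS
BEGIN IONS
TITLE=decoy:1
PEPMASS=456.158818
CHARGE=3+
RTINSECONDS=1755.9801
END IONS
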