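# Published counts and signed positions (relative to the translation start
# codon; -1 adjacent to the ATG) of the ART1-binding GGNVS cis-element in the
# 1500 bp promoters of the eight aluminum-detoxification-subgroup (C4-3)
# soybean MATE genes. Positions refer to occurrences on the promoter sense
# strand; one row per gene, positions comma-joined as printed.
gene_id	count	positions
GmMATE13	7	-639,-943,-944,-1149,-1150,-1398,-1451
GmMATE47	12	-232,-541,-548,-670,-769,-834,-1026,-1043,-1044,-1183,-1417,-1457
GmMATE58	5	-42,-122,-133,-1447,-1481
GmMATE74	7	-85,-287,-768,-1210,-1354,-1386,-1390
GmMATE75	12	-383,-609,-611,-612,-616,-884,-885,-1002,-1003,-1015,-1351,-1449
GmMATE79	15	-139,-143,-144,-260,-489,-513,-560,-590,-637,-724,-725,-990,-1139,-1283,-1446
GmMATE84	9	-271,-772,-893,-1150,-1177,-1287,-1443,-1444,-1445
GmMATE87	11	-141,-376,-515,-516,-636,-671,-813,-1010,-1162,-1235,-1491
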