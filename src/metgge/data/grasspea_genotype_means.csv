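genotype,name,status,origin,DTM,BY,SY,BLPSI
G1,BANG-113-S5,Germplasm,Bangladesh,118,6.75,1153.49,1264.74
G2,32-GP-F3-S2,Germplasm,Nepal,118,7.84,1424.25,1534.04
G3,BANG-147-S3,Germplasm,Bangladesh,117,6.59,1195.74,1305.90
G4,32-GP-F3-S5,Germplasm,Nepal,120,7.10,1469.45,1582.23
G5,BANG-188-S4,Germplasm,Bangladesh,119,7.13,1154.06,1266.06
G6,39-GP-F3-S2,Germplasm,Nepal,121,8.34,1341.17,1453.58
G7,BANG-277-S1,Germplasm,Bangladesh,119,7.68,1395.31,1507.01
G8,40-GP-F3-S3,Germplasm,Nepal,120,8.20,1320.93,1432.48
G9,BANG-233-S1,Germplasm,Bangladesh,120,8.09,1289.89,1401.55
G10,FLRP-B38-S5,Advanced breeding line,ICARDA,119,6.74,1613.23,1724.99
G11,40-GP-F3-S6,Germplasm,Nepal,119,6.71,1302.11,1414.53
G12,BANG-234-S1,Germplasm,Bangladesh,117,6.46,1153.26,1263.80
G13,FLRP-B54-1-S2,Advanced breeding line,ICARDA,115,7.23,1740.25,1848.02
G14,48-GP-F3-S3,Germplasm,Nepal,119,7.74,1519.10,1630.49
G15,BANG-271-S2,Germplasm,Bangladesh,119,8.03,1286.40,1397.50
G16,21-GP-F3-S5,Germplasm,Nepal,120,7.07,1064.53,1177.71
G17,48-GP-F3-S10,Germplasm,Nepal,119,7.53,1450.54,1562.01
G18,BANG-288-S2,Germplasm,Bangladesh,119,9.26,1503.74,1612.98
G19,23-GP-F3-S1,Germplasm,Nepal,119,7.30,1174.82,1286.40
G20,48-GP-F3-S15,Germplasm,Nepal,120,8.64,1488.27,1599.13
G21,BANG-307-S2,Germplasm,Bangladesh,118,7.19,1382.04,1493.10
G22,23-GP-F3-S2,Germplasm,Nepal,119,10.51,1213.38,1321.87
G23,74-GP-F3-S1,Germplasm,Nepal,118,6.82,1091.02,1203.45
G24,BANG-307-S3,Germplasm,Bangladesh,119,7.41,1269.14,1380.73
G25,23-GP-F3-S5,Germplasm,Nepal,119,8.57,1224.43,1334.86
G26,74-GP-F3-S5,Germplasm,Nepal,119,7.19,1035.71,1148.52
G27,BANG-27-S2,Germplasm,Bangladesh,119,6.67,1156.34,1268.30
G28,25-GP-F3-S3,Germplasm,Nepal,120,9.81,1285.19,1395.13
G29,BANG-31-S6,Germplasm,Bangladesh,119,6.76,1255.60,1367.97
G30,31-GP-F3-S2,Germplasm,Nepal,118,7.76,1222.84,1333.08
G31,BANG-15-S1,Germplasm,Bangladesh,117,7.37,1062.22,1173.10
G32,31-GP-F3-S4,Germplasm,Nepal,120,9.16,1616.97,1727.31
G33,31-GP-F3-S7,Germplasm,Nepal,121,7.54,1620.68,1733.64
G34,IGC-2012-70/1-8,Advanced breeding line,ICARDA,119,6.65,915.09,1028.82
G35,IGC-2012-31/2-37,Advanced breeding line,ICARDA,119,8.13,907.65,1021.40
G36,IGC-2012-6/3-36,Advanced breeding line,ICARDA,118,8.24,1057.88,1167.89
G37,IGC-2012-78/4-19,Advanced breeding line,ICARDA,120,8.69,1080.97,1193.41
G38,IGC-2012-76/5-42,Advanced breeding line,ICARDA,120,7.44,1072.42,1186.36
G39,IGC-2012-4/6-50,Advanced breeding line,ICARDA,119,6.67,1122.80,1235.38
G40,IGC-2012-2/8-8,Advanced breeding line,ICARDA,121,7.95,1399.11,1511.66
G41,IGC-2012-74/10-7,Advanced breeding line,ICARDA,119,7.26,1222.34,1333.71
G42,IGC-2012-88/11-50,Advanced breeding line,ICARDA,118,7.82,1138.27,1250.58
G43,IGC-2012-24/12-43,Advanced breeding line,ICARDA,118,6.98,924.70,1037.72
G44,IGC-2012-31/2-1,Advanced breeding line,ICARDA,117,7.75,758.32,871.70
G45,IGC-2012-6/3-42,Advanced breeding line,ICARDA,119,7.86,1046.71,1159.48
G46,IGC-2012-78/4-5,Advanced breeding line,ICARDA,118,7.37,905.93,1020.31
G47,IGC-2012-76/5-14,Advanced breeding line,ICARDA,121,9.94,1154.18,1265.12
G48,IGC-2012-4/6-8,Advanced breeding line,ICARDA,119,7.04,1148.55,1260.64
G49,IGC-2012-74/10-41,Advanced breeding line,ICARDA,119,7.93,1154.61,1265.81
G50,IGC-2012-24/12-26,Advanced breeding line,ICARDA,119,7.86,1034.07,1146.34
G51,IGC-2012-70/1-5,Advanced breeding line,ICARDA,117,7.51,979.95,1090.82
G52,IGC-2012-6/3-39,Advanced breeding line,ICARDA,119,9.69,1299.26,1408.57
G53,IGC-2012-31/2-44,Advanced breeding line,ICARDA,118,9.91,1315.60,1423.57
G54,IGC-2012-6/3-47,Advanced breeding line,ICARDA,118,7.11,961.53,1073.80
G55,IGC-2012-4/6-23,Advanced breeding line,ICARDA,117,7.36,1061.78,1174.67
G56,IGC-2012-14/7-44,Advanced breeding line,ICARDA,119,8.86,1396.80,1506.57
G57,IGC-2012-2/8-35,Advanced breeding line,ICARDA,118,5.70,1376.27,1488.20
G58,IGC-2012-73/9-5,Advanced breeding line,ICARDA,119,8.01,1329.43,1440.42
G59,IGC-2012-74/10-1,Advanced breeding line,ICARDA,121,8.17,1193.07,1306.15
G60,IGC-2012-6/3-43,Advanced breeding line,ICARDA,118,7.02,1254.02,1365.38
G61,IGC-2012-24/12-24,Advanced breeding line,ICARDA,118,7.68,868.99,983.69
G62,IGC-2012-67/13-25,Advanced breeding line,ICARDA,119,7.76,1278.61,1391.98
G63,Mahateora,Released variety,India,117,6.65,1440.39,1550.37
G64,Prateek,Released variety,India,118,7.79,1684.00,1794.34
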