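specimen_id,age_label,bw_g,vl_mm3,va_mm3,sa_mm2,diam_um,diam_sd,septum_um,septum_sd
2095d,13dpc,,0.63,,,,,,
2095e,13dpc,,0.48,,,,,,
2095f,13dpc,,0.36,,,,,,
2095g,13dpc,,0.66,,,,,,
2350_1,neonate,0.13,1.73,0.57,42.68,294,70,42,11
2350_3,neonate,0.13,1.98,0.91,40.14,351,97,40,11
2350_7,neonate,0.13,2.74,1.39,46.95,403,87,41,13
2257_4,4dpn,0.21,4.35,1.74,100.99,259,51,33,10
2257_6,4dpn,0.21,4.19,1.64,87.85,258,76,34,9
2257_3,4dpn,0.21,4.83,2.00,106.70,257,77,34,12
2383_2,7dpn,0.28,5.63,2.29,153.16,196,57,25,11
2383_4,7dpn,0.27,5.56,2.23,182.87,187,80,22,8
1993_2,11dpn,0.69,20.58,4.68,273.14,148,38,25,7
2419_3,11dpn,0.45,14.84,5.92,227.73,140,46,26,10
1993_3,11dpn,0.73,21.42,4.77,317.88,135,40,23,10
1994_8,14dpn,0.99,27.78,9.98,409.45,132,30,26,6
1994_9,14dpn,0.98,24.87,12.11,699.04,137,28,27,5
1994_10,14dpn,1.03,24.64,7.72,368.44,110,28,24,7
2040,21dpn,2.43,71.14,20.88,877.41,106,23,23,3
2037,21dpn,2.34,58.84,23.84,1220.42,116,29,16,4
2036,21dpn,2.26,51.42,23.68,1755.55,101,26,16,4
2059,28dpn,4.22,208.62,68.79,3570.22,80,14,19,5
2060,28dpn,4.16,189.75,76.69,3676.58,98,18,20,5
2065,35dpn,7.25,388.59,143.07,9606.84,85,18,17,5
2405,35dpn,6.08,344.00,144.51,7616.83,61,15,10,3
2194,35dpn,7.68,493.68,184.93,9982.44,64,16,20,4
2049,49dpn,13.64,504.03,201.78,13703.22,58,10,16,4
2402,49dpn,11.59,452.65,237.29,15529.72,50,12,9,2
2403,49dpn,11.09,408.96,236.15,16672.78,47,11,10,2
2179,57dpn,31.58,1176.68,372.105,18896.72,63,11,9,2
2413,57dpn,14.81,663.60,353.06,22073.97,44,9,9,2
2416,57dpn,18.53,790.89,352.45,24499.42,47,9,12,2
2095,adult,87.22,2948.94,1396.63,43744.40,61,15,11,3
2117,adult,69.47,2307.41,914.69,31591.77,81,16,10,3
2419,adult,66.46,2631.63,1387.20,40383.30,94,20,10,3
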