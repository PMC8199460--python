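subject,seq,sel_task1,sel_task2,sel_task3,sel_task4,sel_total,min_actions,time_task1_s,time_task2_s,time_task3_s,time_task4_s,time_total_s,accuracy_pct
S1,3,19,2,29,21,71,67,304,32,464,336,1136,98.59
S2,4,31,3,28,31,93,57,591,57,534,591,1773,78.5
S4,4,23,3,27,28,81,62,438,57,514,533,1542,86.42
S5,5,20,3,23,24,70,55,444,67,510,533,1554,88.57
S6,4,23,2,25,22,72,63,441,38,479,422,1380,93.06
S7,8,25,3,24,39,91,59,789,95,757,1231,2872,80.22
S8,3,30,3,28,52,113,65,475,48,444,824,1791,70.8
S9,6,19,2,28,22,71,60,485,51,714,561,1811,92.96
S10,4,19,3,23,39,84,57,362,57,439,744,1602,85.71
S12,3,21,2,21,26,70,61,335,32,335,414,1116,94.29
S13,3,23,2,50,37,112,73,365,48,794,588,1795,75
S14,4,25,2,16,24,67,55,476,38,305,457,1276,89.55
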