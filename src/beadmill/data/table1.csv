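run,feed_rate_ml_h,bead_load_pct,cell_load_od600,run_time_min,cod_g_L
1,300.00,60.00,50.00,20.00,1.76
2,500.00,60.00,50.00,20.00,0.79
3,300.00,80.00,50.00,20.00,1.46
4,500.00,80.00,50.00,20.00,0.84
5,300.00,60.00,70.00,20.00,2.51
6,500.00,60.00,70.00,20.00,0.85
7,300.00,80.00,70.00,20.00,2.26
8,500.00,80.00,70.00,20.00,0.82
9,300.00,60.00,50.00,30.00,1.95
10,500.00,60.00,50.00,30.00,1.07
11,300.00,80.00,50.00,30.00,2.27
12,500.00,80.00,50.00,30.00,1.63
13,300.00,60.00,70.00,30.00,2.97
14,500.00,60.00,70.00,30.00,1.23
15,300.00,80.00,70.00,30.00,3.28
16,500.00,80.00,70.00,30.00,1.88
17,258.58,70.00,60.00,25.00,2.15
18,541.42,70.00,60.00,25.00,0.84
19,400.00,55.86,60.00,25.00,1.84
20,400.00,84.14,60.00,25.00,1.64
21,400.00,70.00,45.86,25.00,1.73
22,400.00,70.00,74.14,25.00,2.58
23,400.00,70.00,60.00,17.93,1.26
24,400.00,70.00,60.00,32.07,2.26
25,400.00,70.00,60.00,25.00,2.28
26,400.00,70.00,60.00,25.00,2.77
27,400.00,70.00,60.00,25.00,2.23
28,400.00,70.00,60.00,25.00,2.20
29,400.00,70.00,60.00,25.00,2.36
30,400.00,70.00,60.00,25.00,2.30
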