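# Box-Behnken design, 3 factors, 5 center replicates, 17 runs
# factors: temperature_C (25/30/35), acn_pct (60/65/70), pH (3/5/7)
# responses: Rs (USP resolution between the two peaks), Rt (retention time, min)
std,run,temperature_C,acn_pct,pH,Rs,Rt
15,1,30,65,5,3.22,2.514
14,2,30,65,5,3.22,2.514
13,3,30,65,5,3.22,2.514
10,4,30,70,3,2.25,1.785
8,5,35,65,7,1.11,2.714
1,6,25,60,5,3.84,3.416
3,7,25,70,5,2.12,1.81
9,8,30,60,3,4.25,3.318
2,9,35,60,5,1.05,3.205
5,10,25,65,3,4.54,2.874
12,11,30,70,7,1.82,1.824
4,12,35,70,5,1.98,1.802
11,13,30,60,7,0.98,4.281
16,14,30,65,5,3.22,2.514
6,15,35,65,3,3.08,2.415
17,16,30,65,5,3.22,2.514
7,17,25,65,7,0.88,3.198
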