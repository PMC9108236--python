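patient,rep_obs1,rep_obs2,dice,h_ave_mm
1,1,1,0.86,1.4
2,1,1,0.87,1.4
3,1,1,0.92,0.6
4,1,1,0.82,1.7
5,1,1,0.88,1.1
1,1,2,0.87,1.2
2,1,2,0.94,0.8
3,1,2,0.87,1.1
4,1,2,0.83,1.7
5,1,2,0.95,0.4
1,1,3,0.85,1.5
2,1,3,0.89,1.4
3,1,3,0.91,0.8
4,1,3,0.88,1.3
5,1,3,0.90,0.9
1,2,1,0.83,1.7
2,2,1,0.88,1.5
3,2,1,0.85,1.3
4,2,1,0.84,1.6
5,2,1,0.90,0.9
1,2,2,0.86,1.5
2,2,2,0.90,1.3
3,2,2,0.90,0.8
4,2,2,0.78,2.1
5,2,2,0.88,1.1
1,2,3,0.84,1.6
2,2,3,0.93,0.9
3,2,3,0.95,0.3
4,2,3,0.75,2.3
5,2,3,0.91,0.8
1,3,1,0.87,1.3
2,3,1,0.86,1.9
3,3,1,0.98,0.2
4,3,1,0.80,1.9
5,3,1,0.98,0.2
1,3,2,0.82,1.7
2,3,2,0.98,0.2
3,3,2,0.92,0.7
4,3,2,0.77,2.2
5,3,2,0.90,1.0
1,3,3,0.89,1.1
2,3,3,0.97,0.4
3,3,3,0.91,0.8
4,3,3,0.91,2.1
5,3,3,0.93,0.7
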