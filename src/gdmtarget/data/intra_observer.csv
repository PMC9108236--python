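patient,observer,rep_a,rep_b,dice,h_ave_mm
1,1,1,2,0.83,1.6
2,1,1,2,0.84,2.1
3,1,1,2,0.91,0.7
4,1,1,2,0.92,0.8
5,1,1,2,0.86,1.2
1,1,1,3,0.84,1.6
2,1,1,3,0.87,1.6
3,1,1,3,0.91,0.8
4,1,1,3,0.87,1.5
5,1,1,3,0.88,1.1
1,1,2,3,0.88,1.1
2,1,2,3,0.92,1.0
3,1,2,3,0.90,0.8
4,1,2,3,0.87,1.4
5,1,2,3,0.91,0.8
1,2,1,2,0.91,0.9
2,2,1,2,0.97,0.4
3,2,1,2,0.90,0.9
4,2,1,2,0.76,2.3
5,2,1,2,0.95,0.5
1,2,1,3,0.94,0.7
2,2,1,3,0.91,1.3
3,2,1,3,0.98,0.2
4,2,1,3,0.69,3.1
5,2,1,3,0.92,0.7
1,2,2,3,0.92,0.8
2,2,2,3,0.90,1.4
3,2,2,3,0.89,1.0
4,2,2,3,0.87,1.6
5,2,2,3,0.97,0.2
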