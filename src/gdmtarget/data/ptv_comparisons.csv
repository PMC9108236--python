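label_a,label_b,p1,p2,p3,p4,p5,p6,p7,mean_printed,sd_printed
1_PTV_GDM,PTV,0.58,0.72,0.73,0.71,0.82,0.83,0.73,0.73,0.083
2_PTV_GDM,PTV,0.59,0.78,,0.75,0.87,0.70,,0.74,0.103
1_PTV_GDM,2_PTV_GDM,0.86,0.87,,0.92,0.94,0.87,,0.89,0.036
1_PTV_GDM,PTV_MIM,0.71,0.75,0.83,0.81,0.86,0.90,0.84,0.81,0.065
1_PTV_GDM-SUM,PTV_MIM,0.77,0.71,0.89,0.85,0.84,0.90,0.85,0.83,0.068
2_PTV_GDM,PTV_MIM,0.71,0.76,,0.85,0.88,0.77,,0.79,0.069
2_PTV_GDM-SUM,PTV_MIM,0.79,0.72,,0.84,0.88,0.78,,0.80,0.061
1_PTV_GDM,PTV_VELO,0.80,0.84,0.84,0.84,0.90,0.92,0.80,0.85,0.046
1_PTV_GDM-SUM,PTV_VELO,0.85,0.88,0.83,0.87,0.91,0.91,0.86,0.87,0.030
2_PTV_GDM,PTV_VELO,0.77,0.86,,0.85,0.91,0.80,,0.84,0.054
2_PTV_GDM-SUM,PTV_VELO,0.80,0.86,,0.87,0.90,0.86,,0.86,0.036
PTV_MIM,PTV_VELO,0.85,0.73,0.90,0.92,0.84,0.87,0.81,0.85,0.063
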