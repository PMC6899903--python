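domain,classification,length,precision,meff
T0950-D1,FM,342,94.20,111
T0953s2-D2,FM,111,100.00,180
T0953s2-D3,FM,93,93.75,180
T0957s1-D1,FM,108,36.36,43
T0957s2-D1,FM,155,87.10,37
T0960-D2,FM,84,17.65,70
T0963-D2,FM,82,11.76,58
T0968s1-D1,FM,119,54.17,116
T0968s2-D1,FM,116,39.13,229
T0969-D1,FM,354,98.59,645
T0975-D1,FM,293,80.70,4918
T0980s1-D1,FM,105,100.00,50
T0981-D2,FM,80,31.25,6
T0986s2-D1,FM,155,80.65,56
T0987-D1,FM,185,100.00,23
T0987-D2,FM,207,92.50,23
T0989-D1,FM,134,55.56,65
T0989-D2,FM,112,43.48,65
T0990-D1,FM,76,37.50,31
T0990-D2,FM,231,36.17,31
T0990-D3,FM,213,55.81,31
T0991-D1,FM,111,0.00,1
T0998-D1,FM,166,44.12,8
T1000-D2,FM,431,95.95,873
T1001-D1,FM,139,10.71,11
T1010-D1,FM,210,88.10,89
T1015s1-D1,FM,88,27.78,580
T1017s2-D1,FM,128,72.00,87
T1021s3-D1,FM,178,94.12,979
T1021s3-D2,FM,101,15.00,979
T1022s1-D1,FM,156,90.62,1393
T0949-D1,FM/TBM,139,100.00,6067
T0953s2-D1,FM/TBM,44,66.67,180
T0958-D1,FM/TBM,77,100.00,22
T0970-D1,FM/TBM,97,88.24,43
T0978-D1,FM/TBM,413,87.80,1602
T0981-D3,FM/TBM,203,100.00,6
T0986s1-D1,FM/TBM,92,73.68,187
T0992-D1,FM/TBM,107,100.00,436
T0997-D1,FM/TBM,185,94.59,963
T1005-D1,FM/TBM,326,93.94,872
T1008-D1,FM/TBM,77,6.25,5
T1019s1-D1,FM/TBM,58,50.00,267
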