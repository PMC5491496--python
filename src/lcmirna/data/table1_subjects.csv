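sample_id,group,age,pmi,sex,ph,rin
C01,control,66,4.5,M,6.87,7.56
C02,control,44,5.0,F,6.75,7.32
C03,control,53,5.0,M,6.58,7.23
C04,control,60,5.0,M,6.88,7.19
C05,control,52,2.5,M,6.98,7.41
C06,control,72,5.5,M,6.89,7.28
C07,control,65,1.0,M,6.88,7.06
C08,control,74,3.0,M,6.98,7.34
C09,control,89,1.5,F,6.57,7.80
C10,control,80,5.5,M,6.92,7.05
C11,control,81,5.0,M,6.77,7.22
S01,case,42,3.0,F,6.67,7.36
S02,case,52,3.0,M,6.94,7.27
S03,case,35,2.0,M,7.01,7.44
S04,case,39,12.0,F,6.88,7.16
S05,case,30,4.0,F,6.72,7.83
S06,case,71,1.0,M,6.69,7.43
S07,case,66,10.0,M,6.86,7.44
S08,case,31,7.0,M,6.91,7.16
S09,case,41,10.0,M,6.45,7.43
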