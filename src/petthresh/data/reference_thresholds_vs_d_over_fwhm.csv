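d_over_fwhm,threshold_percent
0.2,95
0.5,74
1,44
1.5,33
2,31
2.5,33
3,35
3.5,36
4,38
4.5,39
5,40
5.5,41
6,42
7,42
8,43
15,43
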