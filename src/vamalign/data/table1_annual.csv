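year,population,mean_midpoint,mean_mle,linf_vs_prev
1997,75242,1.36833,1.62673,
1998,73940,2.05077,2.22051,
1999,70316,2.04756,2.19150,0.01263
2000,74962,2.05653,2.17430,0.01135
2001,67811,2.05691,2.15717,0.00941
2002,69715,2.03665,2.12588,0.00395
2003,63852,2.05765,2.13179,0.01431
2004,71137,2.01045,2.06681,0.00875
2005,74616,1.93659,1.94131,0.01437
2006,77411,1.98527,1.99804,0.01634
2007,76808,1.97690,1.98742,0.00266
2008,76503,2.03243,2.05356,0.01216
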