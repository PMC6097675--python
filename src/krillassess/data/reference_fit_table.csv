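config,n_pars,median_iterations,pct_best,nll,max_g,delta_aic,delta_bic,coda_pass
cfgI,48,1,100,17247,3.51e-05,11616,11474,True
cfgII,49,1,100,14223,2.16e-05,5570,5431,True
cfgIII,49,1,100,16528,4.19e-05,10180,10041,True
cfgIV,49,1,100,17070,3.02e-05,11264,11125,True
cfgV,49,1,100,17106,2.50e-05,11336,11197,True
cfgVI,51,1,80,13604,1.06e-06,4336,4203,True
cfgVII,54,1,100,16368,3.14e-05,9870,9746,True
cfgVIII,63,13,5,13446,3.67e-03,4044,3946,False
cfgIX,90,1,30,13692,3.42e-05,4590,4572,True
cfgX,91,1,95,12054,7.05e-06,1316,1301,True
cfgXI,91,1,100,11766,1.91e-05,740,725,True
cfgXII,92,1,95,11766,2.72e-05,742,730,False
cfgXIII,93,1,95,11643,9.36e-06,498,489,True
cfgXIV,94,1,55,11487,1.52e-05,188,182,True
cfgXV,96,1,15,11417,6.66e-05,52,52,True
cfgXVI,96,1,27,11391,3.77e-05,0,0,True
cfgXVII,104,3,30,11384,4.52e-05,2,26,False
cfgXVIII,104,19,40,12342,4.10e-05,1918,1942,False
cfgXIX,105,8,10,11540,7.06e-02,316,343,False
cfgXX,106,2,25,11386,5.84e-05,10,40,False
cfgXXI,107,2,35,11383,2.25e-05,6,39,False
cfgXXII,107,2,15,11383,1.92e-05,6,39,False
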