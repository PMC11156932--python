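eddy_id,variable,anomaly
0,nasc_epipelagic,0.5694121674327633
0,nasc_mesopelagic,0.5694121674327629
0,sst,0.016975769996545154
0,chl,-0.149678285407307
2,nasc_epipelagic,0.041604048562271845
2,nasc_mesopelagic,0.04160404856227151
2,sst,0.015440864397177068
2,chl,-0.13813039419387485
3,nasc_epipelagic,0.5714191942794986
3,nasc_mesopelagic,0.5714191942794986
3,sst,0.018881539042163276
3,chl,-0.1709993642505654
4,nasc_epipelagic,0.00400575277471471
4,nasc_mesopelagic,0.004005752774714988
4,sst,0.016496986403133684
4,chl,-0.1623415704147494
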