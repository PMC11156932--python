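polarity,variable,n_eddies,pct_increase,mean_anomaly_increase,abs_mean_anomaly_increase,pct_decrease,mean_anomaly_decrease,abs_mean_anomaly_decrease,pct_null,mean_anomaly_null,abs_mean_anomaly_null
AE,chl,4,0.0,,,100.0,-0.15528740356662415,0.15528740356662415,0.0,,
AE,nasc_epipelagic,4,50.0,0.5704156808561309,0.5704156808561309,0.0,,,50.0,0.022804900668493278,0.022804900668493278
AE,nasc_mesopelagic,4,50.0,0.5704156808561307,0.5704156808561307,0.0,,,50.0,0.02280490066849325,0.02280490066849325
AE,sst,4,100.0,0.016948789959754795,0.016948789959754795,0.0,,,0.0,,
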