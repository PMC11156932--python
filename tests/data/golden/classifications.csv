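eddy_id,variable,outcome,p_value,statistic,n_inside,n_outside,polarity
0,nasc_epipelagic,increase,3.1242511774807024e-19,19.438253562294484,101,131,AE
0,nasc_mesopelagic,increase,3.1242511774807024e-19,19.438253562294484,101,131,AE
0,sst,increase,3.606072406843782e-22,20.994044574351477,101,131,AE
0,chl,decrease,3.1928778374601226e-09,-12.840007307270735,101,131,AE
2,nasc_epipelagic,null,0.34974844225188906,2.4531994047619046,168,168,AE
2,nasc_mesopelagic,null,0.34974844225188906,2.4531994047619046,168,168,AE
2,sst,increase,1.0158254624699882e-27,28.626562500000002,168,168,AE
2,chl,decrease,2.7641975638130907e-11,-17.469047619047622,168,168,AE
3,nasc_epipelagic,increase,7.384598935103594e-15,2387.0,82,83,AE
3,nasc_mesopelagic,increase,7.384598935103594e-15,2387.0,82,83,AE
3,sst,increase,1.0089114221869694e-17,2631.0,82,83,AE
3,chl,decrease,7.920453225375745e-09,-1771.0,82,83,AE
4,nasc_epipelagic,null,0.9433572583391264,-0.17090336134453776,137,143,AE
4,nasc_mesopelagic,null,0.9433572583391264,-0.17090336134453776,137,143,AE
4,sst,increase,2.2594551789451433e-25,25.037079831932772,137,143,AE
4,chl,decrease,1.6567777218690725e-11,-16.19642857142857,137,143,AE
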