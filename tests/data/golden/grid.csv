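cell_lon,cell_lat,n_eddies,n_significant,pct_significant
-144.0,-33.0,1,0,0.0
-141.0,-39.0,1,0,0.0
-138.0,-24.0,1,1,100.0
-129.0,-27.0,1,1,100.0
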