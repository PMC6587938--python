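sample_id,domain,sequences,otus,shannon,chao1,ace
Tx001,Archaea,802,743,5.24,211.9,239.55
Tx002,Archaea,1439,1292,5.15,159.1,218.11
Tx003,Archaea,571,518,5.01,113.1,165.55
Tx004,Archaea,160,152,5.61,147.8,175.18
Tx005,Archaea,837,775,5.33,132.1,164.38
Tx006,Archaea,723,685,4.79,105.5,145.56
Tx007,Archaea,1365,1144,5.87,259.6,355.46
Tx008,Archaea,1225,1187,2.10,56.6,86.20
Tx009,Archaea,802,750,5.66,162.1,182.63
Tx010,Archaea,1112,1011,4.72,180.0,216.98
Tx011,Archaea,826,785,5.31,299.7,257.60
Tx012,Archaea,630,623,2.87,30.0,31.56
Tx013,Archaea,927,868,5.60,162.4,228.47
Tx001,Bacteria,668,511,5.52,323.00,222
Tx002,Bacteria,676,558,5.92,349.14,337
Tx003,Bacteria,436,346,5.96,207.43,223
Tx004,Bacteria,323,309,6.12,178.06,227
Tx006,Bacteria,231,217,5.74,130.08,133
Tx007,Bacteria,794,706,6.21,197.24,224
Tx008,Bacteria,304,266,5.72,93.25,128
Tx009,Bacteria,700,641,6.11,168.35,182
Tx010,Bacteria,297,278,5.52,132.33,138
Tx011,Bacteria,245,220,5.75,129.50,144
Tx012,Bacteria,280,232,5.57,70.00,74
Tx013,Bacteria,167,155,6.13,126.00,131
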