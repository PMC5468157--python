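reserve,current_km2,future_km2,ac_pct
Banqiao,309.20,242.23,-21.66
Changqing,307.21,295.96,-3.66
Foping,300.00,300.00,0.00
Guanyinshan,148.44,148.44,0.00
Hanzhongzhuhuan,0.00,0.00,
Huangbaiyuan,210.79,210.79,0.00
Huangguanshan,81.28,129.75,59.64
Laoxiancheng,120.57,120.57,0.00
Motianling,47.56,0.00,-100.00
Niangniangshan,96.49,75.24,-22.02
Niubeiliang,0.00,0.00,
Panlong,158.13,102.10,-35.44
Pingheliang,12.36,58.54,373.63
Sangyuan,120.05,9.05,-92.46
Taibainiuweihe,106.98,102.77,-3.94
Taibaishan,348.93,269.28,-22.83
Tianhuashan,273.31,285.90,4.60
Yingzuishi,5.78,41.33,615.41
Zhouzhi,322.31,290.50,-9.87
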