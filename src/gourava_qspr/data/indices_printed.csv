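molecule,GO1,GO2,HGO1,HGO2,AGO1,AGO2,GGO1,GGO2
glycine,28,93,1177,16280,181,914,489,3184
alanine,135,448,1915,3364,271,1562,771,5752
serine,145,462,2055,35404,285,1664,793,6086
aspartic acid,168,560,2390,41200,326,1912,888,6896
isoleucine,181,602,2567,43468,351,1438,781,7322
threonine,187,650,2793,52588,375,2312,1075,8654
glutamic acid,199,728,3128,58384,416,2560,1170,9464
valine,219,784,3391,67832,451,2858,1335,10888
methionine,223,752,3207,56056,459,2666,1351,9992
glutamine,223,770,3305,60654,441,2586,1063,9890
leucine,261,952,4129,85016,541,3500,1617,13456
lysine,285,1040,4507,91672,886,3798,1713,14456
arginine,296,1082,4414,88978,584,3592,1640,13172
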