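molecule,Da,MP,Pl,pKa1,pKa2,HI,A3,LogP,D,FP,pH
glycine,75.07,233,5.97,2.34,9.6,-0.4,60.1,-1.39,1.1607,7,0
alanine,89.09,258,6.01,2.34,9.69,1.8,88.6,-2.83,1.424,7.5,41
serine,105.09,246,5.68,2.21,9.15,-0.8,89,-1.75,1.603,7.5,-5
aspartic acid,133.1,270,2.77,1.88,9.6,-3.5,111.1,-1.67,1.7,5,-55
isoleucine,131.18,285.5,6.02,2.36,9.68,4.5,166.7,0.41,1.207,5.5,99
threonine,119.12,265,5.6,2.09,9.1,-0.7,116.1,-1.43,1.3,6,13
glutamic acid,147.13,199,3.22,2.19,9.67,-3.5,138.4,-1.39,1.4601,6.5,-31
valine,117.15,298,5.96,2.32,9.62,4.2,140,-0.01,1.316,6.5,76
methionine,149.21,281,5.74,2.28,9.21,1.9,162.9,-0.56,1.34,2.5,74
glutamine,146.15,185,5.65,2.17,9.13,-3.5,143.8,-2.05,1.47,4,-10
leucine,131.18,293,5.98,2.36,9.6,3.8,166.7,-1.62,1.17,9,97
lysine,146.19,224.5,9.74,2.18,8.95,-3.9,168.6,-1.15,1.1,6,-23
arginine,174.2,260,10.76,2.17,9.04,-4.5,173.4,-1.43,1.5,5,-14
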