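parameter,value
D_A,1.18412
sigma_Ax,5.65390
sigma_Ay,3.80360
D_B,1.28421
sigma_Bx,8.20823
sigma_By,2.41578
a,10
b,4
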