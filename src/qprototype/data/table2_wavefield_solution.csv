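k,item,x,y,monomial,F
1,Almond,-7.2826,3.24347,1,87.6039
2,Acorn,-7.3316,2.3116,x,2792.02
3,Peanut,-5.2957,4.56032,y,8425.01
4,Olive,-4.3776,3.41765,x^2,19.36
5,Coconut,-5.0322,1.24573,x*y,-2139.87
6,Raisin,-2.7149,0.896651,y^2,-7322.26
7,Elderberry,-1.420,0.487598,x^3,-39.2811
8,Apple,0,0,x^2*y,-55.5263
9,Mustard,1.7978,7.64549,x*y^2,586.674
10,Wheat,2.4786,7.73915,y^3,2205.81
11,Root Ginger,2.8164,7.41004,x^4,-2.22868
12,Chili Pepper,3.9933,7.03549,x^3*y,4.19408
13,Garlic,4.7681,7.81803,x^2*y^2,13.3579
14,Mushroom,5.6281,6.89107,x*y^3,-72.233
15,Watercress,7.233,6.67322,y^4,-275.834
16,Lentils,8.1373,6.56281,x^5,0.426731
17,Green Pepper,3.8337,5.55379,x^4*y,1.58764
18,Yam,1.5305,4.69497,x^3*y^2,0.582536
19,Tomato,2.4348,2.42612,x^2*y^3,-1.13167
20,Pumpkin,3.9873,2.06652,x*y^4,3.44008
21,Broccoli,10,4,y^5,12.2584
22,Rice,11.6771,0.392458,x^6,-0.00943132
23,Parsley,11.3949,-0.268463,x^5*y,-0.0535881
24,Black Pepper,11.9389,-0.107151,x^4*y^2,-0.200688
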