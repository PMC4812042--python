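item,mu_A,mu_B,mu_AorB,lambda_pub,lambda_rank_pub,epsilon_pub,phi_deg_pub
Almond,0.0359,0.0133,0.0269,0.0217,16,1,84.0
Acorn,0.0425,0.0108,0.0249,0.0214,17,-1,-94.5
Peanut,0.0372,0.0220,0.0269,0.0285,10,-1,-95.4
Olive,0.0586,0.0269,0.0415,0.0397,9,1,91.9
Coconut,0.0755,0.0125,0.0604,0.0260,12,1,57.7
Raisin,0.1026,0.0170,0.0555,0.0415,7,1,95.9
Elderberry,0.1138,0.0170,0.0480,0.0404,8,-1,-113.3
Apple,0.1184,0.0155,0.0688,0.0428,5,1,87.6
Mustard,0.0149,0.0250,0.0146,0.0186,19,-1,-105.9
Wheat,0.0136,0.0255,0.0165,0.0184,20,1,99.3
Root Ginger,0.0157,0.0323,0.0385,0.0172,22,1,49.9
Chili Pepper,0.0167,0.0446,0.0323,0.0272,11,-1,-86.4
Garlic,0.0100,0.0301,0.0293,0.0146,23,-1,-57.6
Mushroom,0.0140,0.0545,0.0604,0.0087,24,1,18.5
Watercress,0.0112,0.0658,0.0482,0.0253,13,-1,-69.1
Lentils,0.0095,0.0713,0.0338,0.0252,14,1,104.7
Green Pepper,0.0324,0.0788,0.0506,0.0503,4,-1,-95.7
Yam,0.0533,0.0724,0.0541,0.0615,3,1,98.1
Tomato,0.0881,0.0679,0.0688,0.0768,1,1,98.5
Pumpkin,0.0797,0.0713,0.0579,0.0733,2,-1,-103.5
Broccoli,0.0143,0.1284,0.0642,0.0423,6,-1,-99.5
Rice,0.0140,0.0412,0.0248,0.0238,15,-1,-96.7
Parsley,0.0155,0.0266,0.0308,0.0178,21,-1,-61.1
Black Pepper,0.0127,0.0294,0.0222,0.01929,18,1,86.7
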