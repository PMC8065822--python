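variable,Afroblepharida,Blepharidina,Calotheca,Searsia,Commiphora
BIO1,24.40,23.07,19.35,17.99,23.81
BIO2,11.41,11.27,12.86,12.53,13.13
BIO3,68.83,66.89,61.32,57.43,61.61
BIO4,157.48,151.94,299.71,337.97,281.59
BIO5,33.04,31.12,29.00,28.17,33.73
BIO6,16.22,14.07,7.53,6.12,12.06
BIO7,16.82,17.05,21.47,22.05,21.68
BIO8,24.87,23.83,21.28,19.29,25.59
BIO9,23.05,21.43,16.30,15.70,20.74
BIO10,26.30,24.61,22.58,21.78,26.83
BIO11,22.43,20.98,15.38,13.60,19.99
BIO12,667.36,1130.15,747.79,693.88,560.66
BIO13,159.74,228.47,132.35,120.40,133.12
BIO14,7.19,8.28,12.83,13.35,4.14
BIO15,96.83,87.83,71.22,66.86,106.76
BIO16,344.36,575.02,349.32,326.07,332.65
BIO17,29.36,36.01,48.71,47.84,16.50
BIO18,184.91,305.68,265.82,239.17,211.67
BIO19,60.39,61.76,88.54,103.94,34.83
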