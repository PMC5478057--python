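model	deviance	parameters	dAIC	weight
phi(juv: year; ad: blythii ., myotis cockchafer)	8747.12	52	0.00	0.261
phi(juv: year; ad: .)	8749.19	51	0.07	0.251
phi(juv: year; ad: blythii cockchafer, myotis .)	8748.47	52	1.35	0.132
phi(juv: year; ad: cockchafer both)	8746.72	53	1.60	0.117
phi(juv: blythii cockchafer, myotis year; ad: blythii ., myotis cockchafer)	8746.43	54	3.31	0.049
phi(juv: blythii year, myotis cockchafer; ad: blythii ., myotis cockchafer)	8746.73	54	3.62	0.043
phi(juv: blythii cockchafer, myotis year; ad: .)	8749.20	53	4.08	0.034
phi(juv: cockchafer both; ad: blythii ., myotis cockchafer)	8765.89	45	4.78	0.024
phi(juv: blythii cockchafer, myotis year; ad: cockchafer both)	8746.16	55	5.05	0.021
phi(juv: blythii year, myotis cockchafer; ad: cockchafer both)	8746.31	55	5.19	0.019
phi(juv: blythii cockchafer, myotis year; ad: blythii cockchafer, myotis .)	8748.67	54	5.55	0.016
phi(juv: blythii year, myotis cockchafer; ad: .)	8751.80	53	6.69	0.009
phi(juv: cockchafer both; ad: cockchafer both)	8765.87	46	6.75	0.009
phi(juv: cockchafer both; ad: .)	8770.56	44	7.45	0.006
phi(juv: blythii year, myotis cockchafer; ad: blythii cockchafer, myotis .)	8750.99	54	7.87	0.005
phi(juv: cockchafer both; ad: blythii cockchafer, myotis .)	8770.41	45	9.29	0.003
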