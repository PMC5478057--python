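model	deviance	parameters	dAIC	weight
alpha(a3+spec)	8749.19	51	0.00	0.771
alpha(blythii a3; myotis a3+cockchafer(coh))	8747.92	54	4.73	0.072
alpha(blythii a3; myotis a3+cockchafer(time))	8748.98	54	5.79	0.043
alpha(blythii a3+cockchafer(time); myotis a3)	8748.99	54	5.80	0.042
alpha(blythii a3+cockchafer(coh); myotis a3)	8749.00	54	5.81	0.042
alpha(blythii a3; myotis a3*cockchafer(coh))	8747.83	56	8.65	0.010
alpha(blythii a3; myotis a3*cockchafer(time))	8748.45	56	9.26	0.008
alpha(blythii a3*cockchafer(coh); myotis a3)	8748.92	56	9.73	0.006
alpha(blythii a3*cockchafer(time); myotis a3)	8748.97	56	9.78	0.006
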