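model	deviance	parameters	dAIC	weight
phi(juv: year; ad: spec) psi(juv: .; ad: spec) p(Col*year+rep+spec)	8749.19	51	0.00	0.212
phi(juv: year; ad: spec) psi(a2*spec) p(Col*year+rep+spec)	8745.79	53	0.60	0.157
phi(juv: year; ad: spec) psi(juv: .; ad: spec) p(Col*year*rep)	8710.05	71	0.86	0.138
phi(juv: year+spec; ad: spec) psi(juv: .; ad: spec) p(Col*year+rep+spec)	8749.12	52	1.93	0.081
phi(juv: year+spec; ad: spec) psi(juv: .; ad: spec) p(Col*year*rep)	8709.25	72	2.06	0.076
phi(juv: year+spec; ad: spec) psi(a2*spec) p(Col*year+rep+spec)	8745.61	54	2.42	0.063
phi(juv: year*spec; ad: spec) psi(juv: .; ad: spec) p(Col*year*rep)	8690.11	82	2.92	0.049
phi(juv: year; ad: .) psi(juv: .; ad: spec) p(Col*year+rep+spec)	8754.83	50	3.64	0.034
phi(juv: year; ad: .) psi(a2*spec) p(Col*year+rep+spec)	8751.29	52	4.10	0.027
phi(a2*spec) psi(a2*spec) p(Col*year+rep+spec)	8767.44	44	4.25	0.025
phi(a2*spec) psi(juv: .; ad: spec) p(Col*year+rep+spec)	8771.52	42	4.33	0.024
phi(juv: year*spec; ad: spec) psi(juv: .; ad: spec) p(Col*year+rep+spec)	8731.57	62	4.39	0.024
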