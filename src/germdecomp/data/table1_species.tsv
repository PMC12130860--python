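species	mu_E	mu_OS	P	g	mu	source
Human	6.6e-9	3.63e-10	13	30	1.24e-8	Jonsson+Wu
Chimpanzee	1.07e-8	3.41e-10	14	25	1.44e-8	Besenbacher
Olive baboon	4.59e-9	1.81e-10	5.4	10	5.42e-9	Wu
Olive baboon	5.14e-9	3.15e-10	5.4	10	6.59e-9	Wang
Rhesus macaque	3.78e-9	4.7e-10	3.5	8	5.9e-9	Wang+Bergeron
Owl monkey	4.61e-9	6.27e-10	1	6.6	8.13e-9	Thomas
Domestic cat	5.7e-9	6.37e-10	0.5	3.8	7.8e-9	Wang
Mouse	4.08e-9	1.51e-9	0.15	0.75	4.99e-9	Lindsay
Aye-aye	2.19e-10	1.27e-9	3	4	1.49e-9	Wang
Aye-aye	5.83e-10	8.84e-10	3	4	1.43e-9	Versoza
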