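category	subcategory	complete_kappa	complete_lambda	incomplete_kappa	incomplete_lambda	fragment_kappa	fragment_lambda	total
AL-PCD	AL	160	524	34	63	6	35	822
AL-PCD	AL/MM	29	25	0	4	0	2	60
AL-PCD	AL/CLL	0	2	0	0	0	0	2
AL-PCD	AL/LCDD	1	0	0	0	0	0	1
AL-PCD	AL/WM	2	3	0	0	1	0	6
Other-PCD	MM	595	374	70	83	42	26	1190
Other-PCD	LCDD	29	4	3	0	2	4	42
Other-PCD	POEMS	0	31	0	5	0	13	49
Other-PCD	WM	5	0	0	0	8	0	13
Other-PCD	WM/LCDD	0	0	1	0	0	0	1
Other-PCD	Other	4	0	0	0	3	0	7
Non-PCD	Localized AL	0	1	1	2	0	2	6
Non-PCD	Non-PCD	1051	581	621	346	102	34	2735
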