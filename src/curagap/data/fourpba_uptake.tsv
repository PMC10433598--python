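variant	uptake_before	uptake_after
p.Y80H	0	0
p.G87R	0	0
p.G132V	0	0
p.G253R	0	0
p.G337W	0	15
p.G356V	0	0
p.P382L	0	0
p.P390L	0	0
p.R391W	10	30
p.A404P	10	30
p.G421R	20	20
p.G424D	0	50
p.A448D	0	10
p.C491W	0	0
p.V539I	10	50
p.P544L	25	50
p.P554L	0	50
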