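environment	GL	GW	GLWR	GC	GS
2017EZ	0.561198	0.587232	0.816784	0.435194	0.102882
2017GA	0.790264	0.842533	0.863557	0.750632	0.403186
2018EZ	0.417942	0.593973	0.780337	0.439132	0.220128
2018GA	0.682506	0.755747	0.802726	0.651486	0.519685
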