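cell_type	0	1	2	3+
INP	233	87	21	9
iOSN	166	208	47	15
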