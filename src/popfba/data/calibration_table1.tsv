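gene	mean_count	mean_fluorescence	ratio
YIL084C	162	26.7249	1.18
YKL145W	2114	100.3195	0.62
YHR107C	2317	113.8195	0.78
YEL031W	3125	85.5069	0.72
YBR249C	19459	185.6222	1.94
YHR183W	48926	1128.4	1.69
YLR058C	98940	267.899	2.01
YLR249W	189235	1904.1	0.63
YJL136C	370314	543.9343	0.89
YKL060C	996503	4462.6	0.71
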