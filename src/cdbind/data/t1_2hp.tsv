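# units=s
# description=T1 relaxation times of the hydroxypropylated host, free vs complexed; ranged rows as high-low intervals
label	t1_free	t1_complex
H1"	1.40-1.54	1.39-1.52
H8"	1.72	1.73
H3"	1.23	1.23
H6"	1.44	1.28
H2"-H4"-H5"	1.42	1.20
H7"	1.55	1.55
H9"	1.19	1.20
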