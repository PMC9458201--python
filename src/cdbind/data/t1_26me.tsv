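# units=s
# description=T1 relaxation times of the methylated host, free vs complexed; ranged rows as high-low intervals
label	t1_free	t1_complex
H1	1.36-1.4	1.35-1.4
H3	1.49	1.51
H5	1.41	1.18
H6	1.34	1.12
H2	1.36	1.12
H4	1.35	1.28
H6-O-Me	1.76	1.79
H2	1.51	1.39
H2-O-Me	1.64	1.62
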