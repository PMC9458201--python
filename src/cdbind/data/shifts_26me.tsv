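# units=ppm
# description=1H chemical shifts of the methylated host, free vs complexed; ranged multiplets given as high-low intervals
label	delta_free	delta_complex	multiplicity
H1	5.35-5.09	5.29-5.03	singlet
H3	4.01	4.00	singlet
H5	3.94	3.90	doublet
H6	3.91	3.88	singlet
H2	3.72	3.68	singlet
H4	3.68	3.67	doublet
H6-O-Me	3.59	3.59	singlet
H2	3.49	3.44	singlet
H2-O-Me	3.41	3.42	singlet
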