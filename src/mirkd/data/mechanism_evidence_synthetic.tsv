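feature_id	mature_fc	mature_significant	precursor_fc	precursor_significant
miR-987-5p	16.8	True	12.0	True
miR-277-3p	3.7	True	3.0	True
miR-252-5p	2.1	True	1.1	False
miR-34-5p	1.4	True	2.0	True
miR-317-5p	2.1	True	2.2	True
miR-9b-3p	-1.5	True	-1.6	True
miR-982-5p	-4.4	True	-1.1	False
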