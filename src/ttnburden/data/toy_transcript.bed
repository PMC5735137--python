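# synthetic minus-strand 3-exon transcript for coordinate-mapping examples
chrS	1000	1046	TOY-1	0	-	1000	1046	0	3	9,12,6	0,20,40
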