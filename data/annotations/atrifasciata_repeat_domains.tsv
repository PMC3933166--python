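# Secondary-structure domains of the 199-aa aciniform spidroin repeat unit
# (published NMR/DANGLE assignment of the A. trifasciata recombinant repeat):
# the first three quarters are helix-rich (six helices), the final quarter
# unstructured; helices 5-6 form the major alpha-helical block.
# Columns: name, start, end (0-based half-open, repeat amino-acid coordinates), label
helix_rich_domain	0	150	helix_rich
unstructured_tail	150	199	remainder
major_helical_block	101	151	helix5_6
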