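# Neutral genomic substitution rates (substitutions/site/year) per host
# clade, used by the LTR molecular clock T = (D/R)/2.  Back-calculated
# from published provirus divergence/age pairs; override per analysis.
megabat: 4.0e-10
microbat: 9.5238e-10
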