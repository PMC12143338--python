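# Genes excluded from variable-gene selection (but never from the matrix).
# Class-I MHC region: highly polymorphic across outbred primates, so counts
# against a single reference are unreliable.
HLA-A*
HLA-B*
HLA-C*
HLA-E*
HLA-F*
HLA-G*
MAMU-A*
MAMU-B*
MAMU-E*
MAMU-F*
MAMU-I*
MAMU-AG*
# Ribosomal protein genes: prone to sample-to-sample batch effects.
RPS*
RPL*
MRPS*
MRPL*
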