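# Mapping from annotation-pipeline consequence/location tokens to the internal
# consequence vocabulary.  Editable: annotation dialects differ in spelling.
nonsynonymous SNV: missense
missense: missense
missense_variant: missense
synonymous SNV: synonymous
synonymous: synonymous
synonymous_variant: synonymous
stopgain: nonsense
stop_gained: nonsense
nonsense: nonsense
frameshift deletion: frameshift
frameshift insertion: frameshift
frameshift: frameshift
nonframeshift deletion: inframe_indel
nonframeshift insertion: inframe_indel
inframe_indel: inframe_indel
splicing: splicing_intronic
splicing_intronic: splicing_intronic
exonic;splicing: splicing_exonic
splicing_exonic: splicing_exonic
intronic: intronic
intron_variant: intronic
upstream: upstream
upstream_gene_variant: upstream
UTR5: regulatory
UTR3: regulatory
regulatory: regulatory
intergenic: intergenic
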