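# Co-occurrence of differential CTCF ChIP-seq binding and differential
# DNase-seq read-count signal at CTCF motif sites containing an allelic SNP,
# aggregated over a published survey of 114 cell and tissue types from 166
# individuals (counts from Supplementary Table 11 of that survey).
# n_total: CTCF sites with an allelic SNP; n_signal: sites with differential
# DNase read counts; n_event: sites with differential CTCF binding; n_both:
# sites with both.
field	count
n_total	11355
n_signal	3079
n_event	810
n_both	566
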