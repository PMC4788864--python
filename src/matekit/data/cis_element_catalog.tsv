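# Editable catalog of stress/hormone-responsive promoter cis-elements.
# The consensus strings below are commonly used field approximations
# (PLACEHOLDERS): regulatory databases define several variants per element
# and do not publish a single canonical consensus, so edit these to match
# the element definitions of your database of choice before interpreting
# per-element counts quantitatively.
name	consensus
ABRE	ACGTG
ARE	AAACCA
CGTCA-motif	CGTCA
HSE	AAAAAATTTC
LTR	CCGAAA
MBS	CAACTG
TCA-element	CCATCTTTTT
TC-rich_repeats	ATTTTCTTCA
TGACG-motif	TGACG
WUN-motif	AAATTTCCT
W1-Box	TTGACC
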