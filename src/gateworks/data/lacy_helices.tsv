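# Transmembrane helix ranges for LacY used to derive the gate order parameters.
# RECONSTRUCTED from 2V8N secondary-structure annotations (approximate; the
# gate pairs are insensitive to a few residues at the helix termini).
# Override with your own ranges for production use on real structures.
helix	chain	first_resid	last_resid
TM1	A	8	34
TM4	A	105	129
TM7	A	221	248
TM10	A	310	334
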