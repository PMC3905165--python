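# External reference structures (not bundled)

Two acceptance tests validate gate order parameters and the pore profiler
against real crystal structures. The coordinate files are not redistributed
with this package; download them from the Protein Data Bank and place them
here to enable those tests:

- `4gby.pdb` — XylE, partially occluded (https://www.rcsb.org/structure/4GBY)
- `2v8n.pdb` — LacY, cytoplasmic open (https://www.rcsb.org/structure/2V8N)

Without these files the two crystal-structure tests report a failure stating
what is missing; every other test is self-contained.
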