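# Titin I27 immunoglobulin domain (PDB 1TIT): a water-soluble negative
# control expected to show a clean hydrophobic core.
scale: aggregate
c: 9.0
margin: 0.0
K: 1.0
interface_cutoff: 9.0
units:
  titin:
    select: [A]
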