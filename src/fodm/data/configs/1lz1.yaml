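# Human lysozyme (PDB 1LZ1): water-soluble enzyme with a local discordance
# carried by the catalytic residues E35/D53 and the near-surface C128.
scale: aggregate
c: 9.0
margin: 0.0
K: 1.0
interface_cutoff: 9.0
units:
  lysozyme:
    select: [A]
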