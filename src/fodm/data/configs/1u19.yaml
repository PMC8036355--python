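# Rhodopsin dimer (PDB 1U19), a non-channel transmembrane protein.
scale: aggregate
c: 9.0
margin: 0.0
K: 1.0
interface_cutoff: 9.0
units:
  dimer:
    select: [A, B]
  chainA:
    select: [A]
  chainB:
    select: [B]
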