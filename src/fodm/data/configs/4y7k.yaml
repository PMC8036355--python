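# Mechanosensitive channel MscS, closed form (PDB 4Y7K), pentamer A-E.
scale: aggregate
c: 9.0
margin: 0.0
K: 1.0
interface_cutoff: 9.0
units:
  complete:
    select: [A, B, C, D, E]
  membrane_complex:
    select: ["A:3-95", "B:3-95", "C:3-95", "D:3-95", "E:3-95"]
  cytoplasmic_complex:
    select: ["A:103-252", "B:103-252", "C:103-252", "D:103-252", "E:103-252"]
  membrane_chainA:
    select: ["A:3-95"]
  cytoplasmic_chainA:
    select: ["A:103-252"]
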