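# Small-conductance mechanosensitive channel MscS, open form (PDB 2VV5).
# Heptamer A-G; domain boundaries follow the tabulated ranges (dom1 25-128;
# an alternative dom1 start of 27 circulates in the literature - see docs).
scale: aggregate
c: 9.0
margin: 0.0
K: 1.0
interface_cutoff: 9.0
units:
  complete:
    select: [A, B, C, D, E, F, G]
  dom1_complex:
    select: ["A:25-128", "B:25-128", "C:25-128", "D:25-128", "E:25-128", "F:25-128", "G:25-128"]
  dom2_complex:
    select: ["A:129-181", "B:129-181", "C:129-181", "D:129-181", "E:129-181", "F:129-181", "G:129-181"]
  dom3_complex:
    select: ["A:182-270", "B:182-270", "C:182-270", "D:182-270", "E:182-270", "F:182-270", "G:182-270"]
  dom4_complex:
    select: ["A:271-278", "B:271-278", "C:271-278", "D:271-278", "E:271-278", "F:271-278", "G:271-278"]
  dom1_chainA:
    select: ["A:25-128"]
  dom2_chainA:
    select: ["A:129-181"]
  dom3_chainA:
    select: ["A:182-270"]
  chainA:
    select: [A]
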