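# Helicobacter pylori MscS, closed state (PDB 4HW9), pentamer A-E.
scale: aggregate
c: 9.0
margin: 0.0
K: 1.0
interface_cutoff: 9.0
units:
  complete:
    select: [A, B, C, D, E]
  dom1_complex:
    select: ["A:18-116", "B:18-116", "C:18-116", "D:18-116", "E:18-116"]
  dom2_complex:
    select: ["A:117-171", "B:117-171", "C:117-171", "D:117-171", "E:117-171"]
  dom3_complex:
    select: ["A:172-260", "B:172-260", "C:172-260", "D:172-260", "E:172-260"]
  dom4_complex:
    select: ["A:261-", "B:261-", "C:261-", "D:261-", "E:261-"]
  dom1_chainA:
    select: ["A:18-116"]
  dom2_chainA:
    select: ["A:117-171"]
  dom3_chainA:
    select: ["A:172-260"]
  dom4_chainA:
    select: ["A:261-"]
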