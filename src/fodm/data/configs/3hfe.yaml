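# Trimeric coiled-coil tail of the Kv7.1 (KvLQT1) potassium-channel subunit
# (PDB 3HFE): the trimer shows a channel-like organization a single helix
# cannot.
scale: aggregate
c: 9.0
margin: 0.0
K: 1.0
interface_cutoff: 9.0
units:
  trimer:
    select: [A, B, C]
  chainA:
    select: [A]
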