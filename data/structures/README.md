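# Reference structures

Place PDB entries here (lower-case file names, e.g. `1tit.pdb`, `1lz1.pdb`,
`3hfe.pdb`, `2vv5.pdb`) to enable the reference-structure tests and analyses.
They can be fetched with:

```python
from fodm import fetch_structure
for pdb_id in ["1tit", "1lz1", "3hfe", "2vv5", "4y7k", "4hw9", "1u19"]:
    fetch_structure(pdb_id, "data/structures")
```

Reduced points tables written by `fodm.write_points` (`<id>.points.csv`) are
accepted in place of full coordinate files.
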