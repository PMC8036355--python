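# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical conventions, and what the synthetic tests do and do not
demonstrate.

## Model and assumptions

A structural unit (complex, chain, domain, or fragment) is a point set of
effective atoms — one per residue, the arithmetic mean of the residue's heavy
atoms. The model assumes that for a water-folded globule the hydrophobicity
density over this point set approximates a molecule-sized 3D Gaussian, and
that deviations from it are informative: toward the uniform distribution R
(no organization) or toward the membrane field M (hydrophobic surface, polar
center).

The observed distribution O aggregates pairwise interactions, weighted by
Levitt's polynomial contact function
`w(r) = 1 − ½(7t² − 9t⁴ + 5t⁶ − t⁸)`, `t = r/c`, zero beyond the cutoff.
Each residue pair contributes `(H_i + H_j)·w(d_ij)`; self-interaction is
excluded — with it, every residue would gain a constant `2H_i` that survives
normalization unless all H are equal, blurring the contact structure the
statistic is meant to capture.

The membrane field is `M = [T + K·(T_max − T)_n]_n`. The inner subscript n
normalizes the inverted component *before* the K scaling; the printed
notation of the defining expression is ambiguous on this point, and this
package fixes the convention as: normalize the inverse, scale by K, add to T,
renormalize. With both T and the normalized inverse summing to 1, K = 1
gives exactly `M = (T + inv_n)/2`. Two consequences worth knowing:

- M is an *attenuated* T plus a mild inversion whenever `N·T_max > 2`
  (always true for space-filling units); it raises the rim and flattens the
  center but does not in general make the rim the global maximum.
- If T is exactly uniform the inverse is the zero vector and cannot be
  normalized; the package raises an error rather than inventing a
  convention, since the defining expression is silent there.

RD places O on a 0–1 axis between T and a second reference:
`RD = D_KL(O‖T) / (D_KL(O‖T) + D_KL(O‖Ref))`. The classification boundary
is strict: `RD(T-O-R) < 0.5` → hydrophobic core present; exactly 0.5 → no
core. A unit without a core whose `RD(T-O-M)` exceeds `RD(T-O-R)`
(equivalently `D_KL(O‖M) < D_KL(O‖R)`) is labeled membrane-like.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `c` | 9.0 | Å | Levitt contact cutoff for O |
| `margin` | 0.0 | Å | additive slack on per-axis extent before `/3` |
| `K` | 1.0 | — | membrane coefficient; 0 = pure water environment |
| `scale` | `aggregate` | — | intrinsic hydrophobicity scale |
| `interface_cutoff` | 9.0 | Å | inter-chain contact criterion on effective atoms |

The defining publications of this family of models do not print the
hydrophobicity scale, the cutoff, or the σ rule, so these are package
conventions: `c = 9 Å` is the value customary in this literature; the σ rule
places the unit inside 3σ per principal axis; the default scale averages
three classical scales (Kyte–Doolittle, Eisenberg consensus,
Fauchère–Pliska), each min–max normalized to [0, 1], which damps
single-scale idiosyncrasies; a rescaled Kyte–Doolittle scale is bundled as an
alternative. Every output echoes the scale and parameters used, and RD
values computed under different scales should be compared only qualitatively.

## Numerical conventions

- **Field fit.** Center = mean position; axes = principal components in
  descending variance. Axis signs are fixed deterministically (non-negative
  dot product with the matching global axis; exact ties resolved by the
  first non-zero component; right-handedness restored by flipping the last
  axis), so repeated runs are bit-identical. The fit requires ≥ 3 residues
  and a non-zero extent on every axis; collinear units are rejected unless a
  positive margin is supplied. T itself depends only on the fitted
  ellipsoid, not on the axis sign conventions, and is invariant under rigid
  motion of the unit when the field is refitted.
- **Divergences.** Base-2 logarithms (bits), `0·log(0/q) = 0`. No epsilon
  smoothing: O support outside the reference support raises an error. With
  `c = 9 Å` on connected structures, `O_i = 0` does not occur in practice; a
  hard error is preferable to a silently smoothed divergence.
- **Fragments and elimination.** A fragment evaluated "in parent" inherits
  the parent's T/O/M values at its residues, renormalized over the fragment;
  no new field is fitted. The same machinery implements residue
  elimination. Restricting to the full set is exactly the identity.
  Note that eliminating even a zero-mass residue changes N and therefore
  moves `D_KL(O‖R)` by `log2(N/(N−k))` — RD shifts of order 1/N are
  inherent to the definition, not numerical error.
- **Altloc/residue hygiene.** Highest-occupancy alternate location wins
  (file order breaks ties); waters and unmappable hetero residues are
  excluded and recorded with reasons; MSE and similar residues map to their
  parent amino acids; author numbering is preserved; duplicated residue
  identities keep the first instance.
- **Degenerate inputs.** Single-residue profiles, all-zero O, uniform T
  with K > 0, and RD = 0/0 all raise typed errors rather than returning
  sentinel values.

## Synthetic generators

The generators produce seeded point clouds with known organization so every
metric is testable without structure downloads. Defaults (chosen once, as
study conditions): n = 200 residues, overall radius 18 Å (a realistic
effective-atom cloud for a ~200-residue globular domain), channel lumen
radius 6 Å, hydrophobicity noise sd 0.1.

- **micelle** — isotropic Gaussian cloud (scale radius/3); H proportional to
  the local sampling density, so hydrophobicity is centrally concentrated by
  construction.
- **channel** — the same Gaussian density restricted to a cylindrical shell
  (lumen radius < ρ < radius, height 2 × radius): a protein wall around an
  axial channel, densest at mid-height and thinning outward. H rises with
  the cube root of normalized radial depth: the lumen lining is polar and
  the wall hydrophobic nearly throughout, as in a membrane-buried channel
  wall. The shape of this ramp matters: a *linear* ramp from zero
  concentrates O so strongly at the outer rim — which the extent/3 rule
  necessarily places at 3σ, where M < 1/N — that O lands closer to uniform
  than to the membrane field, an organization the model has no label for
  and real channel walls do not exhibit. The saturating ramp reproduces the
  regime actually reported for channels: no core
  (`RD(T-O-R) ≈ 0.6`) with the membrane signature
  (`RD(T-O-M) > RD(T-O-R)`) in every tested seed.
- **uniform** — uniform ball with constant H: no organization; its RD
  (T-O-R) sits well above the micelle generator's.

What passing these tests shows: the pipeline detects the three organizations
it was built to distinguish, deterministically, across seeds. What it does
not show: performance on real structures. The clouds have no backbone
connectivity, no secondary structure, no side-chain asymmetry, and their H
values are assigned, not taken from a residue scale — so the synthetic study
validates the statistics, not the biology. The published RD values for real
entries (titin, lysozyme, MscS, the Kv7.1 coiled-coil) are asserted in a
dedicated test that runs whenever those entries are present under
`data/structures/`; agreement within ±0.05 is the most that can be expected,
since the reference publications do not print their scale or cutoff.

## Design choices

- Effective atoms use **all** heavy atoms by default; a side-chain-only
  switch is provided because the choice shifts O (glycine falls back to all
  atoms).
- N is the count of resolved residues; residues missing from the crystal are
  simply absent, since every formula operates on resolved effective atoms.
- The 2VV5 domain boundaries bundled in the example config use the
  tabulated ranges (dom1 25–128); a dom1 start of 27 also circulates, and
  the difference is two residues out of ~104 per chain.
- Discordance ranking sorts by |T − O| descending with excess (O > T)
  first on ties, then residue order; excess marks candidate interface or
  membrane-contact residues, deficiency marks cavities and catalytic
  pockets.
- No automatic iterative elimination until RD < 0.5 is performed: there is
  no canonical stopping rule, so elimination is always an explicit request.
- The interface criterion (9 Å between effective atoms) is a package
  default, echoed in reports, since no published value exists for it.

## Known limitations

- RD is sensitive to the fitted field: adding or removing a few extremal
  residues changes the per-axis extents and can move RD by ~0.03 even when
  the residues carry negligible mass. Comparisons are only meaningful under
  a fixed convention (same scale, cutoff, σ rule).
- The membrane coefficient K is user-set, not fitted; K = 1 is the
  convention for membrane channels.
- Scores on NMR ensembles use the first model only.
- The problem sizes in the test suite and acceptance study (n = 200, 50
  seeds) were chosen as the smallest sizes at which the seed-to-seed spread
  of RD is well below the effect sizes being asserted.
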