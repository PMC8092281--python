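# msring

Cyclic-symmetry modelling of the periplasmic region of the bacterial
flagellar MS-ring.

## The problem

The MS-ring is the base of the bacterial flagellum: a transmembrane ring of
a single protein, FliF, whose periplasmic region folds into three
ring-building-motif (RBM) domains (D1, D2, D3).  Native basal bodies show a
striking symmetry mismatch: one ring assembly of 34 identical subunits
displays **C23** symmetry in the inner M-ring, **C11** in the middle region
that surrounds it, and **C34** in the S-ring and its β-barrel collar.  The
34 subunits therefore adopt two distinct conformations (23 + 11 = 34),
related by a hinge rotation of D2 against D1, while all 34 copies
contribute two collar strands each (2 × 34 = 68).

This package re-implements, as a tested pipeline, the hybrid-modelling
procedure by which such an architecture is built from a crystal-structure
subunit and medium-resolution (≈6–9 Å) density maps:

1. **Tentative double ring** — superpose D1 and D2 independently onto the
   subunits of a homologous C24/C24 concentric template double ring
   (injectisome-like), carrying the whole subunit with each anchor:
   24 + 24 = 48 placements.
2. **Inner ring** — resymmetrize the inner 24-mer tier to C23 (the
   reference subunit's pose is preserved bitwise; the other 22 copies are
   regenerated by the C23 operators) and rigid-fit into the density.
3. **Middle region** — prune the outer tier to 11 equiangular members,
   resymmetrize to C11, 11-fold-average the map, and hinge-refit D2 against
   the fixed D1 about the domain-junction CA.
4. **Assembly and validation** — join with the C34 S-ring; report tier
   counts, detected symmetries, diameters, steric clashes, interface
   crosslink distances, linker reach, and the collar strand count.

Symmetry is assigned from density by a **rotational power spectrum**: the
map is resampled on cylindrical shells around the ring axis, the angular
Fourier power is accumulated per fold number, and the dominant fold among
candidates 2–40 identifies Cn (power at fold n and its multiples, never at
proper divisors).

All fitting is deterministic (orientation grid + coordinate descent with
step halving + a Powell polish), scored by masked real-space correlation of
the model's simulated map against the target.

## Worked example

```
$ python analysis/03_build_msring.py
tier counts: inner=23, middle=11, sring=34; total FliF-like subunits = 34
collar strands: 68
steric clashes (<2.2 Å interchain): 0
detected symmetry [inner]: C23 (confidence 70893.532)
detected symmetry [middle]: C11 (confidence 1.943)
detected symmetry [sring]: C34 (confidence 34522.137)
external diameters (nm): {'inner': 14.1, 'middle': 23.6, 'sring': 25.0}
linker reach: {'n_residues': 13, 'required_span': 30.0, 'max_span': 47.19, 'feasible': True}
```

Reading: the pipeline built the two-conformation architecture (23 inner +
11 middle = 34 subunits, all 34 joining the S-ring tier), each tier's
self-simulated map detects its own symmetry order, the model is clash-free,
and a 13-residue linker (max span 13 × 3.63 ≈ 47 Å in extended
conformation) comfortably bridges the ~30 Å gap it must cross — the
measured confidence values are power ratios of the best to second-best
fold.

The numbered scripts under `analysis/` run the full study: `01` generates
the synthetic subunit, templates and planted noisy tier maps; `02` detects
each planted symmetry from the maps; `03` builds and validates the model
above; `04` measures stand-in reference rings at published homolog-ring
diameters (17 / 24 / 21 nm).  Tables land under `results/`.

A `msring` command-line tool wraps the same steps
(`msring fixtures | build | detect-symmetry | fit | validate | simulate-map`).

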