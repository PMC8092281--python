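# Methods

This note documents the models, conventions and numerical choices behind
`msring`, and what the synthetic test conditions do and do not establish
about real data.

## Coordinate model and numbering

Structures are flat ordered lists of atom records grouped into chains;
`(chain_id, residue_index, atom_name)` is unique and iteration order is
input order.  Author residue numbering is the only numbering exposed,
because every residue of interest in the FliF literature (H156, S200, the
C147–C182 disulfide, the i-loop 157–170) is cited in author numbering.  The
two numbering schemes for the N-terminal periplasmic fragment are related
by a fixed +2 offset (Aquifex 58–213 ↔ Salmonella 60–215, no indels).
Alternate locations keep the highest-occupancy conformer, ties going to the
first encountered — a deterministic rule.  PDB/mmCIF parsing and writing go
through gemmi; MRC/CCP4 maps likewise (mode 2 float32, axis order
normalized on read, non-cubic voxels resampled with a provenance note).

Sequence threading is gapless by construction: the backbone is copied
verbatim (backbone RMSD to the template is exactly zero) and side chains
beyond CB are dropped for substituted residues.  At the 6–9 Å resolutions
this pipeline targets, side chains are unresolved, so rebuilding them would
add parameters without information.  Gapless percent identity requires
equal lengths and performs no alignment.

## Rings and symmetry

A ring is a structure plus tier annotations (name, order n, axis,
reference chain, member chains).  Cn operators are rotations by 360k/n
about an arbitrary axis line; they form a group, which the tests assert by
brute force for n ≤ 12.  Axis fitting takes the best-fit-plane normal of
the chain centroids, oriented by the mean N→C vector so the two
antiparallel normals are disambiguated by chain topology.

**Resymmetrization** regenerates a tier at a new order while preserving the
reference subunit bitwise — the other n−1 copies are produced by the new
Cn operators.  Radius is deliberately not rescaled: the operation models
"apply a Cn operation to one subunit of the template ring", so the
reference pose (radius, height, orientation) is the invariant.

**Pruning** to k equiangular members keeps, for each ideal azimuth
(reference azimuth + 360j/k + phase), the nearest unused member.  The
azimuthal phase between tiers of co-prime orders (23:11 has no common
register) is a free parameter, default 0°, recorded in provenance.

**Diameters** are twice the extreme heavy-atom radial distance from the
tier axis (max → external, min → internal), reported in nm to 0.1.
Published "about" values for homolog rings carry no stated definition, so
comparisons use a ±1.5 nm band.

## Density simulation and the rotational power spectrum

Simulated maps stamp one isotropic Gaussian per atom with FWHM equal to
the nominal resolution and integral equal to the atomic number, on a cubic
grid (default voxel 2.0 Å for synthetic work — Nyquist-safe for 6–9 Å
targets).  The map integral therefore equals total Z within 1%, a
closed-form check in the tests.  Simulation is linear in the model.

The rotational power spectrum resamples density on cylindrical rings
(trilinear interpolation; ≥ 4·n_max angular samples, rounded up to a power
of two) over a shell (r_min, r_max, z_min, z_max), takes the angular FFT
power per ring, accumulates with annulus-area (radius) weights, and
normalizes folds ≥ 2 to unit sum.  Folds 0 (mean) and 1 (axis
miscentering) are excluded.  Detection takes the argmax among candidate
folds with ties broken toward the smaller fold; confidence is the
best/second-best power ratio, and results under a threshold (default 1.5)
are flagged ambiguous rather than returned as firm.  A true Cn map has
power at multiples of n, never proper divisors, so the argmax identifies n
itself.  Shells are set per tier from the tier's own radial/axial extent
(±6 Å margins) so coaxial tiers at different radii do not mix.

Noise convention: "SNR s" adds white Gaussian noise with standard
deviation equal to the RMS of the noise-free map over its support (voxels
above 5% of the maximum) divided by s.  This choice is documented here
because no standard definition exists for simulated-map SNR; detection of
planted C11/C23/C34 at SNR 1 and 8.6 Å is robust under it.

Cn averaging rotates the map n times (trilinear) and takes the mean; it is
idempotent to interpolation tolerance and reduces the variance of seeded
noise by ≈ 1/n, verified on smoothed noise fields where interpolation does
not itself destroy variance.

## Fitting

Rigid fitting scores a pose by Pearson correlation between the posed
model's simulated map and the target, over a mask combining the
model-proximal region (4 Å around atoms) with nearby target support
(density above 10% of the maximum within an 8 Å halo of the model).  The
proximal term stops empty box volume from diluting the score; the
nearby-support term penalizes poses that leave adjacent density
unexplained without punishing a subunit for density belonging to its
symmetry mates.  For rigid fits the mask is frozen from the start pose
(dilated to cover the search range): a mask rebuilt per pose jumps as atoms
cross voxel boundaries and creates false plateaus.

The search is fully deterministic: a coarse orientation grid (default 10°
steps) about the start, coordinate-descent refinement (rotation then
translation, halving steps to 0.25° / 0.1 Å, schedule repeated until a full
cycle yields no gain), and a final Powell polish on the 6-dof pose.  The
polish exists because axis-aligned coordinate descent can stall in curved
rotation/translation valleys of the correlation surface; Powell's
direction-set updates follow them.  With it, planted poses within the
coarse basin (≤15°, ≤5 Å) are recovered to well under 1 Å / 3°, and the
40-random-start recovery test passes at 100%.

The hinge refit rotates D2 about the CA of the first D2 residue (the
D1/D2 junction) over a spherical axis grid × magnitude scan with local
refinement, the fixed body being **everything up to the junction** —
D1 plus the linker residue.  Leaving the linker out of the fixed body
leaves its density unexplained and biases the recovered hinge angle by
2–3°; including it makes planted hinges of 10–40° recover exactly.  The
pivot is configurable since no specific pivot atom is canonical.

## Pipeline

The tentative double ring anchors inner placements on D1 and outer
placements on D2, superposed independently onto the corresponding template
ring subunits (CA correspondence by order, trimmed to the common length).
The inner tier is then resymmetrized (24 → 23 by default) and optionally
rigid-fit into a map; the outer tier is pruned to 11, resymmetrized,
hinge-refit in the 11-fold-averaged map, and re-propagated by C11.  The
S-ring tier (C34) is joined coaxially (axes must agree within 2°).  The
subunit total counts the M-ring tiers (23 + 11 = 34); the S-ring tier is
formed by the same 34 subunits' D3 domains, and the collar strand count is
2 per S-ring subunit (68).

Validation computes: heavy-atom interchain pairs under 2.2 Å via a
KD-tree (clashes); CB–CB distances (CA for glycine, CA fallback for
reduced models) for configured residue pairs across adjacent inner-ring
chains, compatible at ≤ 7.0 Å — a deliberately generous cutoff that
accommodates rotamer freedom at medium resolution; per-tier diameters;
per-tier symmetry detection on a self-simulated map (voxel 3.0 Å for
speed); linker reach as n_residues × 3.63 Å/residue (extended-chain
contour) against the required span (13 residues vs ~30 Å is feasible:
47.2 ≥ 30); and the collar strand count.

## Synthetic data: what it emulates, what it does not

Toy subunits are CA/CB reduced models: two compact domains (helix-bundle,
sheet-slab or blob shapes) joined by a single linker residue in a
chain-continuous layout, with D1/D2 annotations and an exact, invertible
hinge construction about the junction CA.  All generators are
bit-reproducible from (spec, seed).  Default study conditions: 20 + 26
residue domains, template double ring C24/C24 at 50/110 Å (placing tiers at
MS-ring-like radii — the derived inner ring measures ≈14–16 nm external),
S-ring C34 at 110 Å radius and +40 Å axial offset, maps at 8.6 Å with
voxel 2.0 Å and SNR 1 noise.

Reduced models exercise all downstream mathematics (fitting at 6–9 Å,
diameters, crosslink-style distances) but not side-chain packing, B-factor
variation, solvent, or the non-white noise and anisotropy of experimental
reconstructions.  Passing tests therefore demonstrate the correctness and
determinism of the procedure, not the fidelity of any particular
experimental model.

Where a published reference object could not be obtained (deposited
crystal structures, homolog rings, experimental maps), measurements run on
**synthetic stand-ins, labelled as such in names and docstrings**, planted
at the published values: a two-chain crystal-like dimer with 0.694 Å
inter-chain CA RMSD (planted orthogonally to rigid motion so superposition
must measure, not remove it), a 156-residue sequence pair at 44% identity
(69/156 matches), and homolog rings at 17/24/21 nm external diameters.
These validate the measurement path end to end; they do not re-measure the
deposited data.

## Problem sizes and known limitations

Synthetic maps run at 96–128 voxels per axis (voxel 2.0 Å) for detection
and 48–96 (voxel 3.0 Å) inside validation and parameter sweeps; the
35-cell order-recovery sweep uses 8+10-residue subunits with a light
refinement configuration, sizes chosen to keep the full study reproducible
on a single CPU in minutes.  Limitations: no dihedral or helical symmetry;
no FSC/resolution estimation or sharpening; single-body and single-hinge
fitting only (no simultaneous multi-body refinement); the azimuthal
register between tiers is a free parameter, not estimated from data; and
the confidence threshold (1.5) is a recorded convention, not a calibrated
statistic.
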