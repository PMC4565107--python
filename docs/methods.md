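# Methods

## Molecular model and contacts

Structures are parsed from PDB text (first MODEL only) into a
Subunit → Residue → Atom hierarchy keyed by (chain, author residue number +
insertion code). Alternate conformers are resolved to the highest-occupancy
atom, ties toward altloc `A`. Waters and unmapped HETATM ligands are
excluded; common modified residues (MSE, SEP, TPO, PTR, SEC, HYP, CSO, KCX,
MLY) map to their parent type; anything else is dropped with a warning.
Hydrogens are kept but flagged and never enter contact or tessellation
computations.

Two contact definitions coexist deliberately:

- **training contacts** — heavy atoms only, strictly `< 6 Å`. These define
  the interface residue pairs used for distribution fitting and for the
  docking energy sum.
- **evaluation contacts** — any atom, inclusive `≤ 6 Å`. These define
  native/predicted contacts for F_nat, F_non-nat and the I_rmsd interface.

Both cutoffs are arguments on every entry point.

## Tessellation

Atoms are weighted Voronoi sites with weight = squared van der Waals radius
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å, default 1.70; table editable).
The power cell of site *i* is the intersection of the halfspaces
`2(c_j−c_i)·p ≤ (|c_j|²−w_j) − (|c_i|²−w_i)` over all *j*, clipped to the
axis-aligned bounding box of the sites expanded by `padding` (default 5 Å).
Each cell is built independently: a Chebyshev-center linear program supplies
a strictly interior point (power cells can be empty — such cells get zero
volume), `scipy.spatial.HalfspaceIntersection` supplies the vertices, and
face polygons are recovered by grouping vertices per generating plane.
For speed only sites within a generous local radius are offered initially;
every vertex of the resulting cell is then verified against *all* sites and
the cell is rebuilt with any violators included, so the final diagram is
exact rather than approximate — cell volumes sum to the box volume to
machine precision (the test bound of 0.1 % is very loose). Cospherical
degeneracies raise a Qhull error and are retried once after a seeded 1e-8 Å
symbolic jitter.

Solvent handling: instead of surrounding the protein with explicit water
sites, cells are clipped to the padded box and box-facing area counts as
solvent-exposed surface. This is deterministic and dependency-free and
preserves the meaning of the surface/total ratio; it over-estimates absolute
exposed area for convex regions, which cancels in the ratio that the
property function uses.

Per-residue aggregation excludes intra-residue atom–atom faces. Each
unordered inter-residue face contributes one shared value (taken from the
lower-index cell) to both directions of the contact map, so
`contact(x,y) = contact(y,x)` holds exactly and
`surface + Σ contact = total` is an identity of the construction; the
two cells' independent polygons for the same plane agree to ~1e-10 Å², well
inside the 1e-6 Å² tolerance asserted at the tessellation level. Contact
areas below 1e-9 Å² are treated as zero.

An independent Monte-Carlo oracle estimates cell volumes by uniform-point
power assignment and face areas by counting points within a thin slab
(half-width 0.05 Å) of the radical plane between the two lowest-power
sites; it reports standard errors and is used only in tests, never by the
pipeline.

## Site features and the neighboring property

The packaged feature table (hydrophobicity = Kyte–Doolittle scale, integer
electrostatic charge, potential hydrogen-bond count per residue type) is
frozen byte-for-byte and guarded by a checksum test. The neighboring
property is computed exactly as printed in the README; neighbors are
restricted by default to the residue's own chain, because p′ describes an
isolated protein before pairing (switchable via `same_chain_only=False`).
A *surface residue* is any residue with nonzero solvent-facing area.
Residues with no tessellation cell (zero total area) raise rather than
silently scoring zero.

## Pair statistics

Per feature, a univariate normal is fitted on the pooled p′ of interface
residues (both sides contribute) and a bivariate normal on the interface
pairs (p′(x1), p′(x2)). Because interfaces have no canonical side order,
pairs enter the bivariate fit in both orders by default, forcing equal
means and standard deviations; `symmetrize=False` gives the raw
maximum-likelihood moments (used when recovering deliberately asymmetric
planted parameters). Fitting requires ≥ 2 complexes and ≥ 30 interface
pairs and rejects zero-variance features by name. Models serialize to a
versioned JSON schema and round-trip bit-identically.

The per-pair energy is the single log-odds term
`s_f = −k_B T · ln(F(x1,x2) / (F(x1)F(x2)))` per feature, combined as
`S = Σ_f w_f s_f` with equal default weights (each 1.0). k_B T defaults to
the dimensionless 1.0 — s_th then lives on the same scale. Densities are
floored at ε = 1e-12 before the logarithm so deep-tail evaluations remain
finite. Under an independent fitted joint (ρ = 0, matched marginals) S is
identically zero, a property the tests assert on a grid.

The neighborhood update adds, for each side, the 1/distance-weighted scores
of all residues with a computed score against the partner residue whose Cα
lies within 10 Å (inclusive) of the pair member's Cα; self-terms are
excluded, residues lacking Cα are skipped with a warning. The update is the
identity in the limit radius → 0.

## Extraction

Pairs with S ≤ s_th are harvested (the harvested set is monotone
non-decreasing in s_th, which is why both the native-contact recovery and
the false-positive fraction rise together as the threshold loosens). Each
interacting residue is ranked by its minimum S′ over its pairs — the paper
of record ranks "interacting residues" without stating the reduction, and
the minimum keeps a residue's strongest pairing decisive; ties break
lexicographically. The `top_k` cap (default 100, "all" supported) bounds
the residues entering clustering. Patches are connected components of the
per-side 10 Å Cα graph ("strongly connected" in the source description is
read as ordinary connectivity — the graph is undirected); components
smaller than `min_patch_size` (default 3) are discarded.

## Docking energies

The structural neighborhood energy of a pose is the sum of S over all
training-contact interface pairs whose residues carry profiles (an S′
variant is switchable). The amino-acid energy is −Σ ln q(type) over
interface residues, with q an interface composition table fitted with
additive smoothing or supplied. π–π, dihedral-angle and side-chain packing
terms are plugin slots satisfying the same `(pose) → scalar` contract;
their published formulas live outside this package's scope. Term values
combine linearly; coefficients are fitted by ordinary least squares on
labelled poses (rank-deficient designs are rejected naming the offending
columns). Pose ranking is a stable ascending sort with unscoreable poses
reported, never dropped silently.

## Evaluation

F_nat = |pred ∩ native| / |native|, F_non-nat = |pred \ native| / |pred| on
evaluation-contact sets. I_rmsd collects the backbone atoms (N, CA, C, O;
missing O tolerated with a warning) of the native-interface residues in
both structures, superposes them with the Kabsch algorithm (proper rotation
enforced via the SVD determinant correction; collinear inputs rejected) and
reports the minimized RMSD. The binding-site P-value is the binomial upper
tail P(X ≥ n), X ~ Binomial(N, m/M), computed with `scipy.stats.binom.sf`
(stable in the far tail); n = 0 returns exactly 1.

## Synthetic data

Generators are pure functions of (parameters, seed).

- **Lattice atoms**: jittered cubic lattice (default spacing 3.0 Å, jitter
  0.4 Å, protein-like inter-atomic distances) with element radii cycled
  through C/N/O/S. Jitter ≥ spacing/2 is rejected as a collision risk.
- **Toy complexes**: two pseudo-protein chains of 5-atom residues (N, CA,
  C, O, CB within 1 Å of the residue center). Residue centers sit 9.5 Å
  apart along the chain axis; a contiguous planted block of ligand residues
  faces its receptor partners at a 4.0 Å offset, the rest at `gap` (default
  20 Å, minimum 12 Å). Geometry guarantees planted pairs are the only
  cross-chain residue pairs with heavy atoms under 6 Å, all others stay
  beyond 8 Å, and consecutive Cα remain within the 10 Å patch-graph radius.
  These chains are deliberately not protein-like in bonding; they exercise
  every algorithm (contacts, tessellation, clustering, superposition)
  without a rotamer library.
- **Property pairs**: correlated samples from a planted bivariate normal
  plus independent decoys from the product of its marginals.
- **Pose sets**: rigid perturbations of the ligand (random axis, fixed
  rotation/translation magnitudes; near < far enforced) with interface
  RMSD labels computed internally.

What passing tests on these fixtures shows: the geometry, statistics,
extraction and scoring machinery compute exactly what they claim. What it
does not show: predictive performance on real proteins, which depends on
training-set scale and genuine physicochemical signal that pseudo-residues
cannot carry.

## Problem sizes and numerical choices

Test fixtures use 5–50 atoms for tessellation exactness (100 seeds), 10⁷
Monte-Carlo samples against 10 small diagrams, 10⁴ samples for parameter
recovery (means within ±0.05, ρ within ±0.03), 12+12-residue toy complexes
for the end-to-end pipeline, and 10-pose sets for ranking enrichment —
sizes chosen so the full suite runs in about a minute while every bound is
meaningfully tight. Face polygons with fewer than three on-plane vertices
contribute zero area; plane membership uses a scale-aware 1e-7 relative
tolerance; the Chebyshev-radius cutoff for declaring a power cell empty is
1e-7 Å.

## Known limitations

- No explicit-solvent tessellation mode ships; box clipping is the only
  solvent treatment (an optional pseudo-water shell was considered and
  documented as future work).
- Marginals are fitted on interface residues only, matching the "one side
  of interface" reading; fitting on all surface residues would change s_th
  calibration.
- Whether a single combined S or per-feature thresholds should drive
  harvesting is ambiguous in the source description; the combined score is
  the default and per-feature weights are configurable.
- Pose generation, side-chain repacking, conformational-change modelling
  and SVM-based final selection are out of scope; the docking module scores
  externally supplied poses.
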