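# Methods

## System and coordinate conventions

The analyses target a dual-membrane junction: a 12-subunit channel whose
pore axis defines z, with the junction midplane (the gap between the two
membranes) at z = 0. Within each membrane the leaflet facing the gap is
extracellular (EC) and the outward leaflet intracellular (IC). All
lengths are Å, all times ns. Density-map origins name the world position
of the *center* of voxel (0, 0, 0); voxel indices are 0-based, subunit
and rod labels 1-based.

## Density maps

Each selected atom is replaced by a normalized 3D Gaussian with standard
deviation equal to the atom's radius; per-frame sums are accumulated on
the grid and averaged over frames, so Σ(grid)·voxel³ equals the mean
selected-atom count per frame. Gaussians are truncated at 4σ by default
(< 0.01% mass loss; configurable, and raised where a test compares
against an untruncated analytic oracle). The radius table defaults to
van der Waals radii (H 1.2, C 1.7, N 1.55, O 1.52, P 1.8 Å) and is
configurable and logged, since visualization tools differ in their
element radii. Maps are resampled trilinearly (0.649 Å default output
voxel, matching the experimental pixel size), averaged voxelwise across
runs on an identical lattice, and symmetrized by averaging over the 12
D6 rotations (6-fold about z plus six 2-folds in the midplane),
evaluated by trilinear resampling of the rotated lattice.

Symmetrization and σ lookups are interpolation-limited: trilinear
resampling of a field with feature scale σ_f on a grid of spacing h
carries a relative error of order h²/(8σ_f²). Tests that assert
symmetry invariance therefore use smooth fields (broad Gaussians) where
that error sits well inside the stated tolerances, rather than loosening
the tolerances.

σ-scaling uses full-grid statistics (no mask), matching common
map-contour conventions; a flat map (sd = 0) raises rather than
returning arbitrary σ values, and positions outside the grid return a
−∞ sentinel that fails every σ ≥ threshold test.

## Order parameters

S_CD = −⟨(3 cos²θ − 1)/2⟩ over all C–H vectors of a carbon and all
frames, with θ measured against the fixed z axis — the junction axis —
rather than per-lipid local normals, consistent with the planar
geometry. Carbon position 1 is the carbonyl (ester) carbon, so "carbons
4–11" indexes the ordered carbon list, not CHARMM atom-name suffixes
(C2x/C3x naming is offset by one — a documented pitfall). Explicit
hydrogens are required; there is no united-atom H reconstruction.

Leaflets are assigned by splitting head-group phosphorus z values at
the three largest sorted gaps into four clusters (each split gap must
exceed 5 Å); within each membrane the cluster nearer z = 0 is EC.
Lipid–protein distance is the minimum heavy-atom distance over all
atom pairs, per frame (the field uses several conventions; this one is
logged and configurable). Shell profiles use contiguous 5 Å bands from
the protein surface; empty shells are reported with n = 0 so profiles
align across runs. Area per lipid subtracts a rasterized protein
footprint (heavy atoms in the leaflet z-slab, dilated by 2 Å on a 1 Å
grid) from the box cross-section and divides by the leaflet count — a
deliberately simple estimator used as an equilibration indicator, not a
Voronoi areal decomposition.

## Configurational states

Rod catalogue: voxels at σ ≥ σ_min (default 8) inside the EC z-slab are
grouped into 26-connected components; components under 20 voxels are
discarded as noise. Components are assigned to subunits by the 30°
angular sector of their centroid and numbered within each subunit by
increasing centroid radius with the radius binned to 2 Å before sorting,
so that hexagonal rows of nearly equal radius are ordered by azimuth
rather than by sub-voxel centroid noise. This numbering is deterministic
and symmetry-consistent across subunits (the original scheme was
arbitrary); when more than 19 components per subunit survive filtering
the catalogue keeps and reports them all.

Occupancy couples region and threshold: a carbon counts toward a rod
when its nearest voxel belongs to the rod's voxel set *and* the
interpolated σ at its position is ≥ σ_min (interpolated σ can dip below
threshold near component edges). A chain occupies a rod at ≥ 5 counting
carbons; if it occupies several, the largest carbon count wins, ties to
the lowest rod label. A lipid's state is the ordered pair "i–j" (SN1
first — configurations sharing acyl positions in reverse are distinct);
both chains in one rod is tracked separately as "degenerate" rather than
folded into "none", so its prevalence stays visible.

The 15 Å protein-proximity filter is evaluated per frame (membership can
toggle). Dwells are maximal runs of identical labels over in-range
frames (duration = frames × 0.1 ns); their durations sum exactly to the
in-range time. A lipid is "stable" when no transition between
pair-states occurs. The census reports occupancy fractions over in-range
frames (summing to 1 including "none"/"degenerate"), mean dwell, and
lipid counts. No kinetic model is fitted beyond these empirical counts.

## Water validation

Criterion 1 is distance-only hydrogen bonding: ≥ 2 N/O partners strictly
closer than 4.0 Å to the water oxygen. The original workflow
supplemented its H-bond tool with visual inspection, which cannot be
encoded; the distance rule is the reproducible core, and angle screening
is left as an extension hook. Criterion 2 requires ≥ 2.5σ in both
half-maps at the oxygen position; criterion 3 requires ≥ 5.3σ in the
experimental map and ≥ 5.0σ in the MD water map. Acceptance requires
criteria 1–2; criterion 3 is advisory and is summarized as the fraction
of accepted waters with an MD counterpart. σ is evaluated at the oxygen
position by point lookup (no peak search radius), the documented
default.

## RMSD / RMSF

Atom pairing matches (chain, residue number, atom name) on the chosen
subset — backbone is N, CA, C, O; a Cα-only mode serves Cα r.m.s.d.
figures — with residues absent from either model excluded and a
chain-order fallback when chain ids differ. Superposition is the
least-squares rigid fit via SVD with the proper-rotation (det = +1)
correction. RMSF replicates are superposed internally onto their
time-average before fluctuations √⟨|x − ⟨x⟩|²⟩ are computed; across the
n replicate values (by default 24 = 12 subunits × 2 runs; the grouping
is configurable) the profile reports mean, sd, and mean ±
t(0.975, n−1)·sd/√n. Symmetry expansion replicates an asymmetric unit
under every group rotation (33 waters → 396), without clash checking.

## Synthetic generator

Lipids are *posed geometrically, not simulated* — the artifact tests
analysis code, not force fields. Defaults mirror the printed system
dimensions: 12 subunits, membrane midplanes ±39.5 Å with ±17.5 Å leaflet
offsets (phosphorus planes near ±22 and ±57 Å, EC head planes framing
the inter-membrane gap), two 14-carbon chains per lipid with explicit
hydrogens, 19 rod sites per 30° sector.

Chain models: a leaflet's chains share a director tilted from z by
|N(0, σ_tilt)| with uniform azimuth; C–H vectors are perpendicular to
the director with uniform azimuth, except a gauche fraction p drawn
isotropically. The planted expectation is closed-form,
S_CD = (1 − p)·(1 − (3/4)(1 − e^{−2σ²}))/2, giving 0.494 for the ordered
EC model (σ = 5°, p = 0, all-trans) and 0.188 for the fluid IC model
(σ = 30°, p = 0.45) — a gel-like vs fluid contrast bracketing the 0.25
threshold. Kinetic lipids hop between rod-pair states under a
row-stochastic Markov chain (default: two states, 2.0 ns mean dwell at
0.1 ns/frame), their chains re-posed onto the planted rod sites each
frame. Water scenes plant true waters (with two O partners at 2.8/3.0 Å
and density peaks) and decoys (neither), with an MD map covering a 76%
subset of the true waters; half-maps add independent Gaussian noise at
1/8 of the peak height, leaving planted peaks ≈ 8σ and decoys in the
noise floor. The rod-map fixture spans the full reconstruction box so
that full-grid σ statistics resemble a real map's, with rod rows placed
clear of sector boundaries.

What the generator does *not* emulate: physical chain packing and
excluded volume, head-group conformational ensembles, solvent dynamics,
membrane curvature, experimental noise spectra (noise is white), and any
coupling between lipid order and the kinetic lipids. Passing tests
therefore demonstrate correctness of the estimators on geometry with
known truth, not force-field realism.

## Problem sizes

The test suite runs small systems (typically 12–30 lipids per leaflet,
6–50 frames) chosen so planted-truth recovery is statistically decisive;
the order-parameter reference computation uses 200 lipids × 100 frames,
and dwell-statistics checks use 50 series × 2000 frames sampled directly
from the Markov model, where posing full geometry would add nothing.

## Known limitations

* Isotropic voxels and orthorhombic boxes only; no PBC wrapping
  (trajectory fixtures are pre-wrapped), no mmCIF, no Fourier-space
  sharpening or FSC.
* Distance-only H-bond criterion (no donor–H–acceptor angle).
* The state classifier's multi-rod tie-break (max carbon count, then
  lowest label) and the per-frame 15 Å membership are documented choices
  where the original description is silent or ambiguous; a
  fixed-membership mode and unordered state labels exist behind flags.
* σ statistics are unmasked; maps dominated by large solvent regions
  will contour differently from masked conventions.
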