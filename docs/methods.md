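# Methods

This note documents the models, conventions, numerical choices and known
limitations of `granulattice`. Lengths are in nm, angles in degrees; the
lab frame is right-handed with z the optical/beam axis; voxel grids are
0-based, indexed (z, y, x), and the physical position of voxel (k, j, i) is
`origin + (i+0.5, j+0.5, k+0.5) · voxel_size`.

## Synthetic assemblies

The generator's defaults are the study conditions: granule diameter
20.1 nm; BCT cell a = b = 27.9, c = 33 nm; triclinic cell a = 28.4,
b = 26.5, c = 24.2 nm, α = 78°, β = 66°, γ = 61°; a five-sector cyclic twin
with wedge angles 76/70/71/73/69° about z; a 600 × 600 × 85 nm volume at
1.1 nm voxels (≈2.4×10³ granules at pure BCT density).

**Lattices.** `build_unit_cell_points` enumerates integer cell translations
(plus centering sites) and keeps points inside an axis-aligned box under a
half-open `lo ≤ x < hi` convention. For boxes commensurate with the lattice
planes this inclusion rule overcounts relative to the volume/primitive-
volume estimate (noticeably for the 85 nm-thin slab, which holds only ~2.6
c-repeats); counts converge to the density estimate for generic origins and
large boxes.

**Twins.** A cyclic twin is specified by wedge angles and one (cell,
orientation) per sector; each sector's lattice is generated over the full
box, anchored at the twin axis, and cut to its azimuthal wedge. The
printed wedge angles sum to 359°; the 1° closure deficit is interpreted
either as angular strain (`closure="stretch_last"`, default — the last
sector widens to close the ring) or as a measurement gap (`closure="gap"`,
an empty 1° wedge). The published data do not distinguish the two.

**Disorder.** Vacancies are independent Bernoulli deletions; jitter is
isotropic Gaussian; bending displaces granules along +x by
`A·sin(2πz/λ)`, emulating the smooth column bending observed along the
beam axis. One integer seed drives all stochastic elements.

**Rendering.** Granules are soft spheres with an error-function edge
profile `0.5·erfc((r−R)/(√2·s))`, s = 1.5 nm by default, so the rendered
FWHM equals the nominal diameter. Linker rods (radius 2 nm, amplitude 0.6)
are drawn between nearest-neighbour pairs (within 1.15× the modal NN
distance) whose connecting vector lies within 10° of a selected lattice
plane. Density accumulates by voxelwise maximum, keeping the intensity
maximum at granule centres. Contrast convention: protein bright. The
optional missing-wedge filter zeroes the Fourier region
`|k_z| > |k_x|·tan(θ)` (tilt axis y) — for dual-axis acquisition the
intersection with the second wedge, i.e. the unsampled pyramid. No
tilt-series simulation or reconstruction is performed; the filter is a
real-space proxy for the reconstruction anisotropy. Membranes, lipid
droplets and cellular context are not rendered; none of the downstream
measurements depend on them.

What the generator does *not* emulate: contrast transfer, dose-dependent
noise correlations, stain granularity, reconstruction artefacts beyond the
missing wedge, or membrane-proximal crowding. Passing tests therefore
demonstrate correctness of the analysis chain under controlled geometry,
not robustness to every property of real tomograms.

## Granule detection and morphometry

Detection is scale-normalized Laplacian-of-Gaussian filtering at
σ = D/(2√3) (the blob-matched scale), an Otsu threshold on the positive
response, local maxima, and greedy non-maximum suppression in **Euclidean**
distance (default separation 0.8×D; a Chebyshev-box suppression would
remove the body-centre sites of a BCT lattice, whose Chebyshev neighbour
distance is much shorter than the Euclidean one). Centres are refined by an
intensity-weighted centroid over one granule radius, giving ≈0.2 voxel RMS
accuracy on noiseless renders.

Diameters are FWHM of background-subtracted line profiles averaged over
the three axes (a 2D in-plane mode mirrors measurements on thin sections);
background is the median intensity in a 1.5–2× radius shell. Profiles that
never cross half-maximum yield NaN.

Group comparison uses one-way ANOVA (`scipy.stats.f_oneway`) and Dunnett's
many-to-one test (`scipy.stats.dunnett`, randomized multivariate-t
integration, seeded). The reference group is user-designated (default:
first). All-identical groups are reported as F = 0, p = 1. A warning (not
an error) flags groups below the 80-granule protocol minimum.

## Unit-cell inference

1. **Neighbour vectors** within 1.6× the modal NN distance (histogram mode)
   are antipodally symmetrized and greedily clustered (15° angular, 20%
   length tolerance).
2. **Primitive basis**: the three shortest non-coplanar cluster centroids
   with |det| above a volume floor, then augmented until every major
   cluster indexes as an integer combination (this absorbs centering
   translations such as the BCT half body diagonal). Fields whose clusters
   are coplanar, or that cannot be indexed by one lattice, raise
   `NoLatticeError`; a fitted lattice whose sites are mostly unoccupied
   (occupancy < 0.6 by convex-hull density) is likewise rejected — that is
   the signature of a lattice-with-basis such as HCP.
3. **Reduction**: the successive minima of the lattice (which in 3D always
   form a basis) give a Buerger cell; signs are normalized toward all-acute
   (Niggli type I) or all-obtuse (type II) scalar products, rows ordered by
   length, right-handed. gemmi's Gruber/Niggli reduction is used in the
   test suite as an independent oracle.
4. **Classification**: integer combinations (coefficients in [−2, 2]) of
   the reduced basis are searched for conventional cells with 1 or 2
   lattice points, right angles (±1°) and edge equalities (±2%) — the
   tolerances match the printed ±1°/±1.1 nm uncertainties. A 2-point
   tetragonal cell containing the half body diagonal is BCT; an all-equal
   1-point cube is cubic-P. FCC is recognized *before* the supercell
   search from its unique 12-vector minimal shell, because the FCC lattice
   also admits a valid 2-point BCT supercell (a/√2, a/√2, a) that would
   otherwise win. With no symmetric supercell the reduced cell is reported
   as triclinic-P, rows ordered a ≥ b ≥ c, angles folded to their acute
   representatives. Two labels with indistinguishable deviation scores
   yield "unclassified" with both candidates listed.

Parameter uncertainties are the standard deviations of realized neighbour-
vector lengths in the cluster matching each conventional edge (≈ σ√2 under
isotropic jitter σ). Residuals are distances to the nearest fitted-lattice
site after a circular-mean phase fit.

**Canonical triclinic caveat.** A hand-drawn primitive cell need not be the
reduced cell of its own lattice. The triclinic parameterization (28.4,
26.5, 24.2 nm; 78/66/61°) contains the shorter lattice translation
|a−b| = 27.912 nm, so every canonical shortest-basis report returns
(27.912, 26.5, 24.2 nm) with acute-equivalent angles (78.0°, 77.5°,
62.86°) — a different, unimodularly equivalent description of the identical
lattice (the test suite verifies the equivalence exactly). Users comparing
against hand-chosen cells should compare lattices, not parameter tuples.

**HCP.** HCP stacking is a lattice with a two-point basis, not a Bravais
lattice; it is flagged separately via its non-centrosymmetric first
neighbour shell (≈half the 12 first-shell vectors lack antipodal partners)
on point sets whose NN-distance distribution is sharp. Random point clouds
are rejected, not labelled HCP.

## Twin analysis

The common axis is initialized as the thinnest principal direction of the
slab-like point cloud and refined as the direction most nearly contained
in all boundary planes (smallest right singular vector of the stacked
normals) — both rotation-invariant.

Per-granule **row orientation** is the azimuth (about the axis, modulo the
local in-plane symmetry: 90° for the BCT square net, 180° for triclinic)
of the granule's dominant in-plane neighbour cluster; ties between
equally-populated row families break to the shortest spacing so all
granules of a net report the same family. Using the dominant cluster
rather than the mean keeps boundary granules from acquiring intermediate
orientations.

**Segmentation** assigns granules to the peaks of a smoothed circular
orientation histogram and splits each orientation mode into spatially
connected components; small domains (<10) are absorbed into their most
connected neighbour. A purely local merge rule ("join neighbours within
tolerance") was rejected: the smooth orientation gradient across a twin
boundary chains adjacent domains together (observed as 5→4 domain fusions
in a third of jitter realizations). The mode-based rule cannot chain.
Limitation: two *adjacent* domains whose lattices share a row orientation
modulo the symmetry would merge; in the five-fold twin all adjacent
sectors differ by ≥14° mod 90°.

Boundary planes are total-least-squares fits to the midpoints of
cross-label contact pairs (within 1.3× modal spacing), excluding midpoints
within two spacings of the apex, where contacts straddle wide azimuth
ranges. Labels are first refined by per-domain lattice residual — a
granule belongs exactly to one sector's lattice, so the residual is a far
sharper boundary criterion than orientation. Wedge angles are the
consecutive azimuthal gaps between boundary traces (direction
`axis × normal`), each refined to the optimal 1D azimuthal separator
between the two domains' granules (margin midpoint): the raw midpoint
cloud carries a half-row localization bias worth ~1–1.5° per wedge.
A boundary whose midpoints straddle the centre (a full plane between two
half-spaces) contributes two antipodal traces, giving the 180°/180° limit.
On the five-sector synthetic twin the maximum per-wedge error is 0.6°
noiseless and ≈1° at 1 nm jitter. Wedge sum plus closure deficit is 360°
by construction for cyclic arrangements.

## 2D class averaging

Boxed particles (default box 2.5× granule diameter ≈ 46 px at 1.1 nm/px)
are normalized to zero mean/unit variance. Initial classes come from
k-means on the leading principal components of the unaligned images; each
iteration aligns every particle to its class average by integer-pixel
cross-correlation (search ±box/4), reassigns by correlation, and
recomputes averages (defaults: 3 classes, 8 iterations; emptied classes
are re-seeded from the worst-fitting particle; bit-reproducible under a
seed). Alignment is translational only, by design: rotational alignment
would destroy the very linker-angle conservation the analysis measures.
Sub-pixel shifts are deliberately not implemented.

Linker directions are peaks of the annular intensity profile between the
granule edge and half the lattice spacing, after sub-pixel re-centring on
the granule centroid (a fraction of a pixel of decentring shears azimuths
by several degrees), 2° circular smoothing, and weighted-centroid peak
refinement (flat-topped ridges otherwise jitter the argmax). Profiles
whose dynamic range is <5% of the image contrast report no linkers.
Antipodal peaks merge into undirected orientations; the primary angle is
the separation of the two strongest orientations (90° for a square net,
with antipodal partners marking the 180° linkers).

## Energetics

The non-retarded equal-sphere Hamaker expression is used with
centre-to-centre distance d (matching how spacings are measured). The
default Hamaker constant A = 1.3×10⁻¹⁹ J lies in the usual
protein-across-water range and reproduces |E| ≈ 0.02 eV at r = 10.05 nm,
d = 25.6 nm; it is a first-class parameter, and a sensitivity scan over
0.5–3×10⁻¹⁹ J is always reported (|E| stays within a factor of ~3).
Axial resolution is the linear model R = r_xy·elongation + alignment
error with the dual-axis elongation factor 1.44 taken as a constant (the
single-tilt elongation formula is not implemented). No dipole–dipole or
many-body model is provided.

## Pipeline and problem sizes

`run_full_pipeline` executes simulate → detect → morphometry → twins →
per-domain lattice fits → class averaging → energetics with stage toggles;
per-stage seeds derive deterministically (SHA-256) from one global seed,
and identical configurations produce byte-identical reports (timestamps
excluded). Class-average particles are picked from the largest twin domain
so the stack shares one row orientation. Stage failures raise with the
stage name after writing the partial report.

Tests and the acceptance script run on desk-scale problems chosen to keep
the full suite in a couple of minutes: lattice recovery on 300–2300-point
clouds, renders of 100–800 granules at 1.1 nm voxels, the full 600 nm twin
as points, and a 300 nm slab render for class averaging; statistical
calibration uses 2000 null and 500 alternative replicates at n = 80 per
group. Domain segmentation degrades when sectors hold fewer than ~150
granules (boundary granules dominate), so twin analyses below a ~340 nm
box are not expected to meet the angle tolerances.
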