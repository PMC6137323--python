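# Methods

`cristamorph` quantifies mitochondrial crista architecture from voxel-wise
compartment segmentations of cryo-electron tomograms, and ships a synthetic
phantom generator that makes every measurement testable by parameter
recovery. This note records the models, the estimators, the tunable
parameters, and the places where a design choice was genuinely open.

## Input model

The pipeline consumes a `LabelVolume`: a 3D integer grid in (z, y, x) order
(z is the tomographic/beam axis) with a closed set of compartment codes —
0 background, 1 mitochondrial outer membrane (MOM), 2 inner boundary
membrane (IBM, the non-crista part of the inner membrane), 3 crista
membrane, 4 intracristal space (ICS, the crista lumen), 5 matrix, 6 matrix
granule. The space between MOM and IBM is unlabelled, like everything
outside the organelle. Voxel size is isotropic, in Ångström, and always an
explicit input (from the MRC header or an override): typical tomogram pixel
sizes after binning are in the 10–25 Å range, and all defaults below assume
that regime.

## Geometric primitives

* **Volumes** are exact voxel counts times the voxel volume; they are the
  oracle that mesh-derived volumes are checked against.
* **Surfaces** are 0.5-level isosurfaces (marching cubes) of the binary
  mask after 2× nearest-neighbour upsampling and Gaussian smoothing of one
  original voxel; summing raw voxel-face areas would overestimate curved
  membranes by ~1.5× through stair-casing, while the smoothed isosurface is
  accurate to a fraction of a percent on a digitized sphere of radius 30
  voxels. Masks too thin to survive the smoothing kernel fall back to the
  raw binary isosurface.
* **Distances** are Euclidean on the voxel lattice (centre to centre),
  reported in Å; connectivity for components is the 26-neighbourhood.

## Per-crista measurements

A crista instance is one 26-connected ICS component; each crista-membrane
voxel joins its nearest lumen component (local distance transforms,
contested voxels to the closer lumen, ties to the lower instance id).
Junction voxels are lumen voxels 26-adjacent to the IBM.

**Base-to-tip axis.** Multi-source geodesic distance is propagated from the
whole junction opening across the lumen; the farthest voxel is the tip
(near-ties, e.g. along a straight distal rim, resolve toward the candidate
centroid so the tip sits mid-rim). The returned polyline is the minimum-cost
path for a cost inversely proportional to the lumen distance transform, so
it runs along the lamella midplane. Medial-axis thinning was rejected: on
slab-like lumens it branches unpredictably.

**Lumen width** at the 10% / 50% / 90% stations of axis arc length is
`2·max(EDT) − 0.5` voxel over lumen voxels within two voxels of the station
point — twice the largest inscribed-sphere radius with a half-voxel
centre-offset correction. Expected error on a slab is within half a voxel.
Station placement avoids the junction flare and the tapering tip; the
endpoints 0%/100% would sit inside both.

**Apex angle.** A 2D cross-section through the tip is sampled in the plane
spanned by the local axis direction and the lamella normal — the plane a
microscopist would draw the angle on. The lamella normal is the smallest
principal axis of the tip-zone lumen cloud; the axis direction points from
the tip to the EDT²-weighted centroid of that cloud (the tail of the medial
path is unreliable here: on large lamellae it can run parallel to the rim
before turning). Each leaflet surface is located per station as the
subvoxel 0.5-crossing of the trilinearly interpolated, lightly smoothed
lumen indicator; one line is fitted per leaflet over the narrowing tip zone
(offsets between 30% and 85% of that leaflet's own plateau, which excludes
both the rounded apical cap and the parallel mid-lamella), and the opening
angle on the luminal side is the sum of the two line inclinations.
Per-leaflet plateau normalization matters: the section plane through the
tip is generally offset from the lamella midplane, so the two leaflets
plateau at different offsets. Recovery accuracy on phantoms is ~1° at 10 Å
voxels and 2–4° at 15–20 Å over the 60°–120° range.

**Junction width** is the inscribed diameter of the IBM opening: the
junction ring is projected onto its best-fit plane and the diameter is
twice the median centre-to-ring distance plus a half-voxel rim correction.
Cristae without IBM contact are reported as detached (NaN) and excluded.

**Resolution gating.** A crista is *well resolved* when its mid-station
width is at least ~3 voxels and its axis arc is at least 3.5× that width.
Shorter, stubbier profiles (grazingly cut or very small organelles) keep
their volumetric measurements but are excluded from station-based and
surface-derived statistics — the in-silico analogue of measuring only
cristae whose profile is properly visible in a micrograph.

## Organelle measurements

Diameter is the minor-axis Feret diameter of the MOM-enclosed region in the
central z slice (rotating calipers on the convex hull, +1 px for pixel
extent); the minor axis is used so tubular mitochondria report width rather
than length, and the major axis is emitted alongside. Cross-sectional area
is the filled MOM contour area in the same slice; an open contour (e.g.
after missing-wedge erosion) is an error rather than a silent underestimate.
The MOM–IBM separation is the mean nearest-membrane distance from every
IBM voxel facing the intermembrane gap, minus one voxel to convert
centre-to-centre into surface-to-surface. The central-slice convention
mirrors restricting analyses to the middle of the tomogram, where the
missing wedge least degrades membranes; `central_crop` implements that
restriction and instance segmentation flags cristae cut by the crop faces.

## 3D aggregates

* **SA/V**: total crista-membrane surface area over total ICS volume.
* **Cristae volume fraction**: (crista membrane + ICS voxels) / matrix
  voxels — exact and voxel-size-free.
* **Lamellarity** (crista shape factor): membrane area / lumen volume per
  crista, in nm⁻¹; the organelle value is the mean over its well-resolved
  cristae.

"Crista membrane surface area" means the area of the luminal leaflet (the
lumen–membrane interface, extracted as the lumen-mask isosurface).
Segmentation membrane thickness is a resolution artifact, and under this
definition an ideal slab of lumen width w has lamellarity exactly 2/w —
the closed form that places 12.0 nm and 16.4 nm lumens at ≈0.17 and
≈0.12 nm⁻¹. Counting both leaflet faces would double every ratio.
Dimensionless "au" variants (physical ratio × voxel size) are emitted per
volume, but cross-organelle comparisons use physical units, since volumes
may differ in voxel size.

## Group statistics

Two-sided Mann–Whitney tests at α = 0.05, exact (full permutation null) for
tie-free samples with n₁+n₂ ≤ 30 and tie/continuity-corrected normal
approximation otherwise. Crista-level metrics (lumen width, apex angle)
are compared over pooled cristae; organelle-level metrics over
mitochondria. No multiple-testing correction by default, matching
per-metric reporting practice; Holm adjustment is available. Pooling
cristae across mitochondria ignores within-organelle clustering — a
limitation shared with the source practice; per-mitochondrion ids are kept
on every crista row so a nested analysis remains possible.

## Phantom generator

Each phantom is a spheroid (or tube) built from nested shells — MOM at the
organelle radius, an unlabelled gap, IBM, matrix — containing lamellar
cristae stacked at distinct levels along the organelle axis. A crista is a
slab of ICS whose distal and lateral rims taper as a symmetric wedge whose
leaflets meet at the apex angle (distal corners rounded so the wedge is
normal to the rim everywhere near the tip), sheathed in crista membrane and
connected to the IBM through a cylindrical junction neck punched through
the shell and capped at the outer IBM surface. Granules are spheres placed
in clear matrix pockets. Everything is deterministic given the seed, and
the emitted ground truth (per-crista realized width, angle, junction
diameter, lumen voxel count, analytic leaflet area) is exact by
construction.

Key defaults: membrane thickness 50 Å (≥1 voxel at the default 10 Å
sampling), inter-lamella spacing ≥1.5 lumen widths membrane-to-membrane and
wide enough for the necks, crista depth 0.8 of the local cross-section
radius, lateral halfwidth solved so the cristae volume fraction hits its
target. When an organelle is too small to host proportioned lamellae
(lateral extent below the wedge taper plus half a lumen width, or below
0.65 junction diameters), it receives fewer — possibly zero — cristae
rather than degenerate slivers.

**Condition presets** encode the two study conditions: control (lumen
120 Å, apex 78°, junction 290 Å, MOM–IBM gap 138 Å, radius 290 nm, cristae
volume fraction target 0.08) and patient (164 Å, 105°, 261 Å, 129 Å,
245 nm, 0.04), with 6 vs 2 cristae at full scale — the patient condition is
cristae-poor. A `radius_scale` argument shrinks the organelle while keeping
crista-scale geometry at the condition values, for desk-scale cohort runs.

**Missing wedge.** `apply_missing_wedge` erodes membrane voxels whose local
sheet normal (estimated by local PCA of the membrane mask) lies within
(90° − tilt half-range) of the beam axis, emulating membranes perpendicular
to the beam being unresolved when tilt collection is restricted to ±70°.
It operates on labels, not in Fourier space: the pipeline consumes
segmentations, and a density-space wedge model is out of scope.

## Cohort model and its calibration

`generate_cohort` draws per-organelle parameters around a preset.
Organelle radius and MOM–IBM gap vary lognormally, driven by one shared
"allometric size" factor per organelle (σ_log 0.8 capped to 0.45–2.0× for
radius; 0.30 capped to 0.5–1.8× for the gap) — spreads consistent with the
0.2–5 μm range of mitochondrial diameters. Junction width varies
independently of size (σ_log 0.36, capped to 0.45–2.2×): it is an
intrinsic neck property, and an independent draw keeps the junction
comparison unbiased when small organelles contribute no measurable
cristae. Crista-scale parameters vary
narrowly (lumen width ±8% per organelle and ±10% per crista, truncated
normal at ±2 SD; apex ±6° per organelle, ±4° per crista; volume-fraction
target σ_log 0.22). Above 1.25× radius the voxel size grows with the
organelle (capped at 1.5×), bounding every grid near the preset's extent —
the same trade a microscopist makes by binning larger tomograms; all
metrics are physical quantities, so this coarsens sampling without
changing units.

These dispersions were fixed by a design-stage power analysis targeting the
study's qualitative finding: at n = 10 vs 10 mitochondria, crista-scale
metrics (lumen width, apex angle, SA/V, volume fraction, lamellarity)
separate the conditions, while organelle-scale metrics (diameter,
cross-sectional area, MOM–IBM distance, junction width) do not. The
reported group dispersions and the reported p-values of the source data are
mutually inconsistent under a normal sampling model (a 490 vs 580 nm
diameter difference with SDs of 40/60 nm would be significant almost
always at n = 10 vs 10); the generator follows the significance pattern and
treats the organelle-scale dispersions as biological spread.
`CohortJitter.reported_dispersion` provides the reported SD/mean ratios for
callers who want them.

## What the phantoms do and do not show

The phantoms reproduce the statistical structure the analysis assumes:
nested closed compartments, lamellar cristae with tubular junctions, known
widths/angles/volumes, realistic size dispersion, and (optionally)
missing-wedge membrane loss. They do not emulate grayscale density, noise,
segmentation error, curved or branched cristae, tubular crista networks, or
membrane thickness variation. Passing recovery tests therefore validates
the measurement definitions and their discretization behaviour — not
robustness to imperfect segmentations of real tomograms.

## Numerical choices and degenerate inputs

Lumen components with fewer than 3 voxels or a degenerate axis are skipped
with a logged reason. Detached cristae report NaN junction width. Volumes
with no cristae report a volume fraction of 0 but NaN (missing, not zero)
SA/V and lamellarity. Station-based tests that cannot find enough usable
leaflet stations raise and the instance's angle is NaN. All tie-breaks
(membrane assignment, tip selection) are deterministic. Problem sizes in
the test suite — half-scale cohort organelles at 15 Å voxels, recovery
phantoms of 100–220 nm radius at 10–15 Å — were chosen so the full suite
validates every claim at desk scale while the estimators stay in the
sampling regime (≥ ~6 voxels per lumen width) where their error terms are
small.

## Known limitations

* The apex-angle definition is a reproducible planar-fit proxy for an
  angle drawn on a 2D slice; whether the original measurements pooled one
  or several slices per crista is not recorded.
* Whether reported "±" dispersions are SD or SEM is not always stated;
  summaries here report both explicitly.
* Lumen width statistics can be pooled per station or averaged per crista;
  both are emitted, and the per-crista mean is used for group tests.
* Cristae pooled across mitochondria are treated as independent in group
  tests (see above).
* The missing-wedge emulation removes labels geometrically; it does not
  model gradual contrast loss or reconstruction artifacts.
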