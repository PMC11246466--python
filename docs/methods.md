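# Methods

## Model

`auxindisk` simulates sepal-primordium patterning on a stage-2 floral
meristem, idealised as a flat disk of polygonal cells that grows, divides,
and patterns itself through polar auxin transport.

**Tissue mechanics.** Cell walls are chains of springs (segments kept at
most 1 µm long).  A spring of rest length L joining vertices at distance r
exerts the strain force k(r/L − 1) on its endpoints along the spring axis.
Uniform turgor pressure acts as an outward normal force P·(wall length)/2 on
each endpoint of every *boundary* wall (it cancels on interior walls).  At
each iteration vertex positions are relaxed to mechanical equilibrium:
implicit (backward-Euler-type) steps of the overdamped dynamics, realised as
damped Newton iterations — the spring-force Jacobian with the transverse
stiffness of compressed springs clamped at zero (so the system matrix is
positive definite), Levenberg-style damping proportional to the local
diagonal stiffness, and a backtracking line search on the potential energy
E = Σ k(r−L)²/(2L) − P·(tissue area).  The overdamped flow decreases E
monotonically, and E is also the step-acceptance metric; the maximum
residual force norm can rise transiently while the boundary load propagates
inward, so it serves only as the stopping criterion (relax_tol).

**Growth.**  Rest lengths extend by their relative stretch times an
extensibility g: dL/dt = g(r − L)/L, applied once per iteration
(dt_growth = 1).  This rate law is stiff for short segments (the relative
rate scales as g/L and a single explicit step is unstable for L < g/2), so
it is integrated with adaptive explicit substeps bounded by half the local
stability limit; a single step reproduces the plain Euler update whenever
that is stable.  Compressed springs shrink their rest length, as the law
dictates.

**Chemistry.**  Each cell carries auxin and CUC concentrations; each wall
segment carries a PIN allocation per incident cell side, and per cell the
allocations sum to 1.  Per chemical substep, computed concomitantly from the
same pre-step state:

* PIN: pin_{i→j} ← (1−α)·pin_{i→j} + α·aux_j^n L_j / Σ_k aux_k^n L_k over
  interior neighbours k, with α = 0.01 and n = 1 below the CUC threshold
  (2 a.u.) and n = 2 at or above it — CUC's sole role is this quadratic
  sharpening of up-the-gradient repolarisation.  If every neighbour has zero
  auxin the target falls back to length-proportional (apolar) shares.  No
  PIN faces the outer boundary and no auxin crosses it.
* Auxin: d(aux_i)/dt = Prod_aux·δ_i − Dec_aux·aux_i +
  Tran_aux·Σ_j(aux_j·pin_{j→i} − aux_i·pin_{i→j})/Area_i with Prod_aux = 1,
  Dec_aux = 0.2, Tran_aux = 400.  δ_i is the per-cell production-noise
  multiplier, drawn at initialisation and each iteration from N(1, SD_aux)
  with negatives clamped to 0 (drawn once only in the frozen-noise variant).
* CUC: d(cuc_i)/dt = Prod_cuc/(1 + (aux_i/K_aux)^hill) − Dec_cuc·cuc_i with
  K_aux = 5, hill = 4, Dec_cuc = 0.2.

Integration: 10 chemical substeps per iteration, each advancing time
dt_chem.  PIN takes exactly one α-step per substep; the auxin/CUC rate
equations are advanced over dt_chem with inner explicit-Euler steps bounded
by half the transport stability limit (dt < 2·Area/(Tran_aux·outgoing PIN)
at the smallest cell), so integration stays stable however small divided
cells get.  Concentrations are clamped at 0 (explicit steps can undershoot;
negative concentrations would corrupt the PIN weights).

**Division.**  A cell divides when its area exceeds 50 µm², by the
minimal-wall-length rule: 180 candidate planes at 1° spacing through the
centroid, the chord of least length winning.  Three Gaussian noise sources
(all SD 2 µm by default) perturb the centre the planes pass through, each
plane's length score, and the junction points along their walls (clamped
inside the wall).  Daughters inherit aux, cuc and δ unchanged; split walls
apportion rest length and PIN proportionally to the new lengths; the new
wall is seeded with PIN 10⁻⁶ per side and each daughter renormalised to a
unit PIN sum.  Numerical guards: a junction landing within 0.1 µm of an
existing vertex reuses that vertex, and a plane whose smaller daughter would
hold under 20% of the parent area is re-chosen noiselessly (or the division
skipped) — sliver daughters otherwise blow up the 1/Area transport term.

**Iteration order** (fixed): relaxation to equilibrium; dilution of aux and
cuc by the relaxation-induced area changes; noise redraw; 10 chemical
substeps; division pass; subdivision of walls over 1 µm; rest-length
growth; reinitialisation (rebuild of cached adjacency and solver
structures); output.

## Genotype presets

Genotypes differ only in (SD_aux, Prod_cuc): WT (0.1, 1), cuc1 (0.1, 0),
drmy1 (1, 1), drmy1_cuc1 (1, 0).  drmy1 is high production noise; cuc1
removes CUC and with it the quadratic PIN-sensitivity branch.

## Calibrated parameters

The printed model fixes the chemical rate constants, the division threshold
and the genotype encodings, but leaves the mechanical scale and the
chemical/growth timescale ratio open.  Choices, made once:

* **Stiffness and pressure.**  Nondimensionalised with k = 1.
  P = 0.002·k gives ~1% mean wall strain on the initial disk.  Because the
  growth law converts strain into exponential areal expansion, strain sets
  the growth rate per iteration; 1% yields a few-fold area growth over 100
  iterations at g = 0.8 and final counts of a few hundred cells, matching
  the magnitudes shown in the source experiments.  (Strains of 5–10% would
  compound to absurd e^10-fold growth.)
* **Chemical substep dt_chem = 0.1** (10 substeps per iteration, so one
  iteration spans one chemical time unit).  This ratio of chemical to growth
  timescales is the regime in which the model behaves as described at its
  source: auxin maxima establish early, while the disk is near its initial
  73-cell size; the wild type forms a small, reproducible number of ring
  maxima (3–4 across seeds); and the high-noise genotype forms widely
  variable counts.  With much smaller steps (0.01–0.02) patterning lags
  growth, maxima emerge late on a several-hundred-cell disk, and the wild
  type itself becomes variable — inverting the noise-robustness contrast
  the model exists to exhibit.  The inner stability substepping (above)
  keeps the integration sound at this step size.
* **Relaxation**: relax_tol = 10⁻⁴·k on the max vertex force norm,
  at most 200 implicit steps (typically <15 are used).

## Initial condition

The packaged disk has exactly 73 cells and 348 wall segments (hence 276
vertices by the Euler relation).  It is a Lloyd-relaxed Voronoi tessellation
of a radius-27 µm disk (cell areas 21–45 µm², all below the division
threshold), with seed points mirrored across the rim so boundary cells are
closed by near-tangent chords, ultra-short construction edges collapsed, and
the rim subdivided so the wall count is exact.  Rest lengths equal current
lengths (unstressed), aux = cuc = 0, δ = 1, PIN apolar.  The generator
(`build_disk`) guarantees approximate counts only; the fixture freezes one
realisation (`scripts/make_fixture.py`).

## Quantification

Auxin maxima: cells at ≥ 30% of the snapshot's maximum auxin (a threshold
in the range over which counts of well-separated maxima are stable — at 50%
a single dominant peak can hide clearly present weaker maxima), grouped
into connected components of the cell-adjacency graph; a component counts
if its auxin-weighted centroid falls in the middle ring (1/3 < r < 2/3 of
the tissue radius, r measured from the area-weighted tissue centroid).  Angular
positions are the components' weighted-centroid angles; robustness is the
coefficient of variation (sample SD / mean) of the circular gaps between
adjacent maxima.  Circular histograms sum intensity in 1° sectors
(counterclockwise from +x, minus an optional alignment offset), aggregated
exactly 4-fold into 90 coarse bins; totals are conserved by construction.
Ensembles are compared with Tukey-HSD pairwise mean tests and
Brown–Forsythe (median-centred Levene) dispersion tests.

## Synthetic data and scope of the tests

All experiments are self-generated: the synthetic tissue is the model's own
state, and ensemble "data" are repeated seeded simulations.  The generator
reproduces the study conditions — the 73-cell disk, genotype noise/CUC
encodings, growth rates 0.4/0.8/1.2, 100 iterations (150 at g = 0.4 and 85
at g = 1.2, calibrated from measured cell counts so final tissues reach
comparable ~450-cell sizes), division at 50 µm².  Note the integrated
growth law saturates for segments shorter than g, so realised growth per
iteration spans a ~1.8× range across g = 0.4–1.2 rather than 3×; the
growth-rate contrast is correspondingly compressed.  It does not emulate 3D dome geometry, cryptic-bract auxin sources,
sequential (outer-before-inner) initiation cues, or imaging noise, so
passing tests show the claimed noise-amplification logic operates in the
model, not that it quantitatively matches real buds.

Ensemble sizes in the test suite are desk-scale: 8 runs per genotype for
the genotype contrasts, 6 per condition for the frozen-noise control, and 6
per extra growth rate — chosen for total suite runtime, with the
directional statistics taking the place of the larger published ensembles.
Directions are asserted with one-sided tests at p < 0.05 where group
differences are the claim, and with variance orderings plus
Brown–Forsythe dispersion tests for the robustness contrasts.

## Known limitations

* 2D disk; no curvature, no third dimension, no anisotropic wall stiffness.
* The three division-noise magnitudes are interpreted here as Gaussian SDs
  (in µm) on the plane centre, the chord-length score, and the junction
  positions; other formulations of "noisy minimal-wall division" are
  possible and would shift division geometry statistics.
* Absolute auxin/CUC units are arbitrary; no calibration to reporter
  intensities is attempted.
* The mechanical solver resolves equilibrium only to relax_tol, so
  trajectories are reproducible per seed but not bit-identical across
  platforms with different BLAS/SuperLU builds.
* Small ensembles (desk scale) mean individual directional tests have
  limited power; effect directions, not effect sizes, are the tested claim.
* The genotype robustness contrast is masked at the maxima-count level by
  division-geometry noise: with the division noise switched off, the wild
  type's final count is perfectly reproducible across seeds while the
  high-noise genotype's varies — the claimed noise-amplification logic —
  but with the default division noise (Gaussian SD 2 µm on the plane
  centre, length score and junctions of ~6 µm cells), division geometry
  perturbs establishment and late-growth maxima insertion in all genotypes
  alike, and count variances of all four genotypes become statistically
  indistinguishable at desk-scale ensemble sizes.  The same churn makes the
  growth-rate sweep inconclusive: variability scales with iterations spent
  growing rather than decreasing at low growth rates.  At the final
  snapshot the maxima are source-limited (each drains a basin of
  production), so mean per-maximum auxin is dominated by how many maxima
  share the tissue, which obscures the CUC intensity effect.
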