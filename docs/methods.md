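# Methods

`histomech` computes apparent (homogenized) elastic properties of
glandular soft tissue from segmented two-dimensional microstructure
images. This note records the models, the numerical choices, and the
limits of what the synthetic-data pipeline can and cannot demonstrate.

## Tissue model

A microstructure is a closed three-phase partition of the image plane:
fibromuscular **stroma** (label 0), the **epithelial compartment**
(label 1) and the **acinar lumen** (label 2). There is no background —
every pixel is tissue. Physical scale enters only through the pixel
size (μm/px). In memory, rasters are indexed `[row, col]` with row 0 at
the image *bottom*, pixel centres at `(j+0.5, i+0.5)·pixel_size`; all
angles are axial (θ ≡ θ+180°), in degrees, counter-clockwise from the
x-axis, normalized to [−90, 90). Files on disk follow the usual
top-row-first viewer convention; readers and writers flip rows.

### Constituent materials

All constituents are hyperelastic and near-incompressible, with
stresses in kPa. Epithelium and lumen are neo-Hookean,

    Ψ_NH = C10·(Ī₁ − 3) + (1/D1)·(J − 1)²,

with Ī₁ the first distortional invariant and J the volume ratio. The
stroma is a Holzapfel–Gasser–Ogden (HGO) material with a single
collagen-fibre family per element,

    Ψ = Ψ_NH + k1/(2k2)·(exp(k2·E²) − 1),
    E = κ(Ī₁ − 3) + (1 − 3κ)(Ī₄ − 1),

where Ī₄ is the squared distortional stretch along the local fibre
direction, k1 (kPa) the fibre stiffness, k2 (–) the exponential
stiffening rate and κ ∈ [0, 1/3] the in-family dispersion. The fibre
term is active only while E > 0: collagen carries no compressive load,
which is the mechanistic source of the tissue's tension–compression
asymmetry. Because the fibre term is O(E²), the energy is C¹ across
the activation boundary; the tangent jump there is accepted.

Per-element dispersion is fixed at κ = 0 (fibres within a sub-region
are treated as perfectly aligned); dispersion at larger scales is
carried by the window-to-window variation of the orientation map
rather than by κ. κ = 1/3 (the isotropic limit, E = (Ī₁−3)/3) is
supported and used as a consistency check.

Near-incompressibility is parameterized by an effective small-strain
Poisson ratio ν (default 0.49) through μ₀ = 2·C10, K₀ = 2/D1 and
K₀ = 2μ₀(1+ν)/(3(1−2ν)), i.e. `D1 = 3(1−2ν)/(2·C10·(1+ν))`. A
published variant of this identity without the factor 2 in the
denominator yields half the intended bulk modulus; the implementation
uses the self-consistent form (verified by a unit test that recovers ν
from (μ₀, K₀)).

Literature parameter ranges used by the sweeps: stroma C10 ∈ [5, 30]
kPa and k1 ∈ [10, 300] kPa with k2 = 200; epithelium Young's modulus
1–40 kPa, converted through C10 = E/(4(1+ν)); lumen C10 ∈ [1.92, 192]
kPa. Sweep grids default to five evenly spaced levels including both
bounds, so the grid midpoints are the benchmark values C10 = 17.5 kPa,
k1 = 155 kPa. Reported conversions of the epithelial range to C10 vary
between sources (the endpoints of one published conversion imply two
different factors); the conversion is therefore an explicit function
(`c10_from_youngs`) rather than a hard-coded table.

## Pipeline

1. **Synthetic microstructure** (`synthetic`). Acini are ellipses
   (lumen core + epithelial ring of fixed physical thickness) placed by
   dart throwing with a hard separating-line non-overlap test plus a
   minimum stromal gap (default `max(3 px, thickness/2)`), which keeps
   the stromal matrix 4-connected. Controls: acinus count, lumen radius
   distribution, ring thickness, elongation (major/minor ratio),
   preferred orientation and Gaussian dispersion. Identical spec + seed
   ⇒ bit-identical raster. Infeasible packings raise, never truncate.
   Fibre fields: `constant` or `channel_tangent` (perpendicular to the
   gradient of the smoothed distance-to-non-stroma transform, so fibres
   follow stromal channels).

2. **Segmentation I/O** (`label_io`). Lossless PNG/TIFF + JSON sidecar
   (pixel size, legend, spec echo). Greyscale threshold segmentation
   maps dark → epithelium, middle → stroma, bright → lumen, matching
   H&E appearance; thresholds are user parameters.

3. **Fibre orientation** (`orientation`). The stroma indicator is
   smoothed (Gaussian, default σ = 2 px), and the 2×2 gradient
   structure tensor is accumulated per non-overlapping window (default
   32 px) over stromal pixels; the local fibre direction is the
   eigenvector of the smaller eigenvalue (along edges/channels), with
   coherence (λmax−λmin)/(λmax+λmin). A band of ceil(3σ)+1 border
   pixels is excluded from the statistics (the filter support leaves
   the raster there). Windows with under 25 % usable stroma inherit
   the nearest valid window (row-major ties). Accuracy on straight
   synthetic channels is ≲1°; stripes within ~1° of a raster axis
   alias into long staircase treads and are only coarsely recovered —
   irrelevant in practice because tissue channels are curved.

4. **Fabric tensor** (`fabric`). Mean intercept length over
   `n_directions` (default 180) directions with one seeded rotational
   offset; parallel lines at 1 px spacing are traversed at a half-pixel
   step, and MIL(θ) = total foreground length / number of runs. Runs
   shorter than 2 px are discarded: the staircase of a rasterized
   boundary sheds spurious short runs that otherwise bias the fitted
   principal axis toward the raster axes by several degrees (measured
   on synthetic ellipses; with the filter the bias is <0.5° and a
   disk's MIL is constant to ~1 %). The antipodally symmetric cloud is
   fitted by an origin-centred ellipse (least squares on xᵀQx = 1; the
   radii are eigenvalue-derived, a ≤ b), avoiding the unstable
   5-parameter conic fit. Degree of anisotropy DA = 1 − a²/b² ∈ [0, 1].
   Collinear clouds degenerate to a = 0 (DA = 1) with the major axis
   along the points; fits with (b−a)/b ≤ 1e−8 are flagged isotropic
   with the principal angle reported as 0 by convention.

5. **RVE construction** (`rve`). The image is rotated by the fabric
   principal angle (nearest-neighbour for labels *and* angles — any
   interpolation would invent phases; carried angles are decremented by
   the rotation), a centred square is cropped, and the fabric analysis
   is re-run: the residual principal angle must stay within 2°.
   Fabrics with DA < 0.1 have no meaningful principal direction and
   pass with a note. The square is then mirrored into a 2N×2N cell
   `[flip_y(M)|flip_y(flip_x(M)); M|flip_x(M)]`, which is exactly
   periodic and mirror-symmetric (perfectly orthotropic); a single
   reflection maps axial angles θ → −θ, the double reflection restores
   them. Mirroring preserves area fractions exactly. The ~1000 μm
   converged window size refers to the pre-mirror ROI; mirroring
   doubles it.

6. **FE homogenization** (`homogenization`). One bilinear quadrilateral
   per (coarsen×coarsen) pixel block; block labels by majority vote
   with ties broken stroma > epithelium > lumen; stromal element angles
   from the orientation map at the block centre (axial block mean as
   fallback). Kinematics are plane stress: each quadrature point
   carries an out-of-plane stretch λ₃ condensed locally from σ₃₃ = 0 by
   a safeguarded Newton on the bracket λ₃ ∈ [0.05, 20] (tolerance
   |σ₃₃| ≤ 1e−12 of the stress scale, with a float64 stagnation exit).
   The condensed in-plane tangent is the static condensation
   Â = A − A(·,33)A(33,·)/A(33,33) of the closed-form total-Lagrangian
   tangent. Because λ₃ relaxes volume change pointwise, bilinear quads
   do not lock at ν = 0.49 and plain 2×2 Gauss quadrature is used —
   no selective/reduced integration is needed under plane stress.

   Periodicity is enforced by a master–slave elimination implementing
   u(x⁺) − u(x⁻) = H·(x⁺ − x⁻) on paired opposite-boundary nodes
   (interior edge pairs plus three corner identifications; 2(N−1)+3
   pairings for an N×N element grid), with the four in-plane macro
   displacement-gradient components H = (H11, H22, H12, H21) as
   reference DOFs and the master corner pinned as the translation
   gauge. Load cases: uniaxial-1/2 and shear-12 at ±5 % (shear applies
   symmetric H12 = H21 = γ/2, avoiding macro rotation). By default the
   uniaxial tests are uniaxial *macro stress* — the transverse normal
   component of H is free with zero conjugate macro force — making
   ⟨σ11⟩/ε comparable to indentation-style moduli; `transverse="fixed"`
   prescribes the full strain tensor instead.

   The nonlinear solves use incremental Newton–Raphson (default 5
   increments) with a secant predictor extrapolating the converged
   state, a backtracking line search on the residual norm, and
   automatic increment halving (≥3 levels) on divergence. Convergence:
   residual below 1e−11 of the increment's force scale, with a
   noise-floor exit (quadratic convergence bottoming out at the λ₃
   condensation tolerance) and a negligible-step exit for vanishing
   loads. At every converged solve the identity ⟨Jσ⟩ = ⟨P⟩·F̄ᵀ (macro
   reaction consistency, the discrete Hill–Mandel statement for PBC)
   holds to ~1e−12 relative and is exposed as
   `CaseResult.hill_mandel_rel`.

   Apparent moduli are secant values at the full test strain:
   E11 = |⟨σ11⟩|/0.05 etc., with ⟨σ⟩ the deformed-volume-weighted
   Cauchy average. Homogeneous cells reproduce the single-point
   plane-stress response to solver precision (~1e−14 relative).

7. **Study driver** (`study`). Full-factorial stromal (C10, k1) sweeps
   and epithelium/lumen sweeps over cohorts of RVEs; benchmark
   selection against the experimental compressive range 20 ± 5 kPa
   (aggregate = mean of E11c and E22c over RVEs; ties toward smaller
   C10 then k1; out-of-range best is returned flagged); OLS regressions
   of the mean apparent modulus (mean of E11, E22 over tension and
   compression) on constituent area fractions with R² = 0 for constant
   responses; per-direction asymmetry indices (Et − Ec)/Ec; two-sided
   Welch t-tests with NS/*/**/*** at .05/.01/.001; CSV/JSON reports
   with deterministic column order.

## What the synthetic generator does and does not emulate

It reproduces the statistical skeleton the mechanics needs: a connected
stromal matrix with oriented channels, epithelial rings around lumina,
controllable area fractions and controllable structural anisotropy. It
does not emulate acinar branching, stain colour/texture, nuclear
detail, open (infolded) lumen shapes, or fraction regimes beyond the
jamming limit of non-overlapping ellipse packing (the epithelial
fraction tops out near ~0.3 here, whereas real prostate sections can
exceed it). Consequences: tests passing on synthetic cohorts show the
*mechanisms* — fibre-driven anisotropy, tension–compression asymmetry,
composition–stiffness correlations — at realistic parameter values;
they do not certify quantitative moduli of real tissue, and findings
that are composition-conditioned (e.g. epithelium being more
influential than lumen) hold in, and are asserted for, the regime where
the epithelial fraction is several times the lumen fraction, as in real
glandular histology.

## Default problem sizes

Chosen to resolve the relevant microstructure while keeping a full
run on one CPU in minutes: fabric/alignment studies use 256×256 px
ROIs at 4 μm (≈1 mm, about the converged RVE window; ~20 acini);
cohort homogenizations use 128×128 px ROIs at 8 μm, mirrored and
meshed at 32×32 elements (128 μm elements). Doubling the mesh to
64×64 elements changes cohort moduli by ≲7 %, well inside the
sign-level questions asked of those runs; `coarsen` exposes the
trade-off to the user.

## Known limitations

* 2D plane stress; no out-of-plane fibre structure, no viscoelasticity,
  strains beyond ~5 % untested (the exponential fibre term with
  k2 = 200 makes larger strains numerically and physically
  extrapolative).
* The acinar lumen is modelled as a soft solid, not a fluid cavity;
  its stiffness range is a literature convention, not a measurement.
* The orientation estimator sees only segmented geometry; it recovers
  channel directions, not sub-resolution collagen texture.
* MIL numbers depend mildly on the line-grid conventions (spacing,
  sampling step, short-run filter); DA values are therefore
  comparable within this implementation, not across tools.
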