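# Methods

## Scope and units

`memfission` analyses near-planar and tubulated lipid membranes from
coarse-grained MD trajectories. It does not run physics: force fields,
integrators and barostats live upstream; the package consumes coordinates
however produced and, for validation, generates kinematic/statistical stand-ins
with known ground truth.

Internal units are Å for length, ps for time, and k_BT for energy at 310 K
(RT = 2.577483411627504 kJ/mol, from the CODATA molar gas constant
8.31446261815324×10⁻³ kJ mol⁻¹ K⁻¹). GROMACS-native quantities convert at the
boundary: nm × 10 → Å; a harmonic force constant k in kJ mol⁻¹ nm⁻² becomes
k/(RT·100) k_BT Å⁻², so 2000 kJ mol⁻¹ nm⁻² ≈ 7.7595 k_BT Å⁻².
Diffusion converts as 1 Å² ps⁻¹ = 10⁴ μm² s⁻¹. Boxes are orthorhombic only;
triclinic input raises an explicit unsupported-format error. Frame indexing is
0-based and times are taken from the file, never re-derived.

## Trajectory model and leaflet assignment

A `FrameSeries` holds T×N×3 coordinates, per-frame boxes, and a constant
`ParticleTable` mapping each bead to a lipid id, species tag and role
(phosphate, headgroup, glycerol, tail, solvent, ion). Each lipid's *reference
bead* is its phosphate; lipids without phosphorus (DAG) fall back to the
headgroup or glycerol bead, logged once. In mixed DOPC/DAG systems this means
the surfaces are defined by the DOPC phosphates plus the DAG glycerol beads;
pass a species filter to restrict to phosphates only.

Leaflet labels (±1, or 0 for unassigned within 2 Å of the surface) come from
either `planar_z` — the sign of the reference bead's z against the global mean,
right for near-planar membranes and exactly translation-invariant — or
`local_midplane`, which grids the membrane in-plane, estimates the mid-plane
per cell as (z_max+z_min)/2 where the cell's z-span shows both leaflets, fills
single-leaflet cells from periodic neighbours, and labels against that local
surface. The local method is required once corrugation amplitude approaches the
monolayer offset; on strongly corrugated test fixtures it labels every lipid
correctly where the planar split misassigns a fifth of them.

Periodic unwrapping applies the minimum-image correction cumulatively per axis;
an exactly half-box step is ambiguous and raises. Unwrap∘wrap is the identity;
MSDs are computed only on unwrapped coordinates.

## Thickness

Per frame the box is divided into nx×ny cells (40×40 default). Thickness per
cell is the difference of the mean reference-bead z of the upper and lower
leaflets in that cell; cells lacking beads in either leaflet are excluded from
the frame mean rather than interpolated, which avoids filling bias in the
observable (the height field, which needs a complete grid, interpolates
instead). The trajectory mean is the mean of frame means; its error is 5-block
block averaging (SD of block means / √5). A 1×1 grid reduces exactly to the
global leaflet-COM separation, which the tests use as a consistency oracle.

## Lateral diffusion

Lipid centres of mass (equal bead masses) are tracked in x,y. The MSD is
averaged over all lipids and all time origins via the FFT autocorrelation
identity, O(T log T) per lipid. `fit_diffusion` fits MSD = 4Dτ + b by ordinary
least squares over a window, by default 10%–50% of the maximum lag — below
that, short-time/ballistic artefacts; above, too few origins. The intercept
absorbs any offset, so affine shifts don't bias D. The quoted stderr comes from
the fit covariance and understates the true uncertainty because MSD points
share underlying displacements; recovery tests therefore check D itself (within
5% at 1000 lipids × 500 frames), not the error bar. A negative fitted slope
reports D_L = 0 with a flag. All lipid species are pooled by default; a species
filter is available.

## Bending rigidity

The mid-plane height h(x,y) per frame is the per-cell average of
(upper COM z + lower COM z)/2 of reference beads, empty cells filled by
periodic nearest-neighbour dilation, per-frame mean removed. The spectrum uses
the raw 2-D DFT ĥ with the continuum normalisation
⟨|h_q|²⟩ = ⟨|ĥ_mn|²⟩·cell_area²/box_area, under which a single cosine mode of
amplitude A carries A²·box_area/4 and equipartition reads
⟨|h_q|²⟩ = k_BT/(A·(K_C q⁴ + σ q²)). Modes are binned by |q| with Δq = 2π/L;
because nearest-integer binning mixes slightly different |q|, each bin reports
the effective q_eff = ⟨q⁻⁴⟩^(−1/4) of its members, which makes a pure q⁻⁴
spectrum exactly unbiased under binning. q = 0 is excluded.

`fit_bending_rigidity` solves the weighted linear problem
1/(s_q·A) = K_C q⁴ + σ q² for q ≤ q_max, weights from the χ² statistics of
mode averages (each Hermitian pair contributes one independent sample per
frame). The tension term is included by default — slab simulations at 1 bar can
carry residual tension — and q_max defaults to the protrusion cutoff
2π/(2·thickness). K_C error is a leave-one-bin-out jackknife. Recovery: within
10% for K_C ∈ {10, 25, 40} k_BT at L = 400 Å, 1000 frames (typically within
1–2%).

## Potential of mean force (WHAM)

The reaction coordinate is the unsigned distance z of the restrained lipid's
headgroup from the bilayer mid-plane (0 = centre, ~40 Å = solvent); a helper
computes it from trajectories, or windows load pre-computed (time, z) text
files. Windows are harmonic, 1 Å apart; the standard self-consistent equations

    p(z_b) = Σ_i n_i(z_b) / Σ_j N_j·exp(f_j − w_j(z_b)),
    f_j    = −ln Σ_b p(z_b)·exp(−w_j(z_b))

are iterated directly (no acceleration, for auditability) until
max|Δf| < 10⁻⁸ k_BT, up to 10⁵ iterations; the |Δf| history is retained as a
convergence diagnostic and is non-increasing on all fixtures.

Two numerical choices matter at stiff force constants (2000 kJ mol⁻¹ nm⁻²
gives window SD σ = 0.36 Å):

1. The equations are iterated on a **0.05 Å internal quadrature grid** and
   aggregated to the reported bin width (0.5 Å default, half the window
   spacing). Iterating directly at 0.5 Å broadens each window by the bin box
   and compresses the whole profile by ≈ Δ²/(12σ²) — 13% at this σ.
2. The bias Boltzmann factor per bin is the **exact Gaussian integral**
   (via the scaled normal CDF, survival-function form in the far tail), not a
   bin-centre evaluation; each reported bin coordinate is the
   density-weighted mean position within the bin.

With both, recovery error scales as 1/√n (verified at 10× samples). At the
well-overlapped protocol (0.776 k_BT Å⁻², i.e. 200 kJ mol⁻¹ nm⁻² at 310 K)
with 5000 exact Boltzmann samples per window, analytic harmonic and
double-well profiles are recovered within 0.15 k_BT on bins holding ≥100
counts. At the stiff 2000 kJ mol⁻¹ nm⁻² constant the adjacent-window overlap
is weak (tails only), and the window-to-window free-energy differences
accumulate a statistical random walk of ~0.2–0.3 k_BT across the 40 Å profile
at that sample size — an information limit of the protocol, not of the
estimator — so the stiff-protocol test uses a 0.35 k_BT tolerance.

Profiles are shifted so min G = 0 (the lipid's equilibrium position, ~15–20 Å
from the centre). Empty interior bins are reported missing, never
interpolated. Errors follow the overlapping-block protocol: the profile is
recomputed on the 50–70, 60–80, 70–90 and 80–100 ns blocks of each window,
each block zeroed at its own minimum; the reported error is the plain SD
across blocks (not SD/√4 — conservative, since the blocks overlap). Barrier
heights are max G on [zero, solvent edge] (extraction) and on
[centre, zero] (flipping).

No autocorrelation correction is applied inside the WHAM weights; the
synthetic windows are i.i.d. by construction, and for real data the block
errors carry the statistical uncertainty.

## Tubulation and fission

The pulled patch is selected by periodic in-plane distance of headgroup beads
from a centre (30 Å default radius, both leaflets). "Elongation" is defined as
the patch headgroup-COM height above the base-membrane mid-plane (a tip-extent
alternative can be derived from `neck_profile`'s slab extents); rates are OLS
slopes over a window.

Fission shows up two independent ways:

- **Changepoint.** The continuous hinge model y = a + bt + c(t−τ)₊ is fitted
  at every interior candidate τ and compared with a single line by an F-test
  with (2, n−4) degrees of freedom. Because τ is chosen by scanning for the
  best fit, the raw p-value is anti-conservative; a Bonferroni correction over
  the candidate set restores control (measured false-positive rate 0/100 null
  traces at α = 0.01). Acceptance additionally requires the post/pre slope
  ratio ≥ 1.5 — fission releases the tube, so the trace must steepen.
  No-detection is a valid result.
- **Topology.** Headgroup beads are clustered per frame by single linkage
  under periodic boundaries (k-d tree within a cutoff, connected components);
  the default cutoff is 1.5× the median nearest-neighbour distance of frame 0.
  Fission is the first frame with ≥2 clusters each holding ≥5% of the lipids,
  sustained for 3 consecutive frames. Note the detection operates on one
  reference-bead surface; for real two-leaflet bilayers pass a cutoff larger
  than the bilayer thickness or filter to one leaflet, otherwise the two
  leaflets count as separate clusters from the start.

The minimum neck radius bins beads above the base membrane into 10 Å slabs
along the normal and reports the smallest RMS in-plane radius about the slab
centroid (the RMS radius of a circle equals its radius). On scripted fixtures
the two detectors agree within 5 frames and each lands within 2 frames / 4 ns
of the scripted severance.

## Synthetic study conditions

The generators are deterministic functions of (parameters, seed); every output
carries a `SyntheticSpec` ground-truth record, and tests read truth only from
that record. Conditions:

- **Flat bilayer**: two single-bead leaflets at ±thickness/2, uniform in-plane
  positions, optional per-frame Gaussian z-jitter. Default separations echo
  the thickness scale of 70:30 DOPC:PA/DAG bilayers (36–41 Å).
- **Helfrich membrane**: per frame, Fourier modes with the equipartition
  variance synthesised from white noise (FFT of real Gaussian noise is
  automatically Hermitian), one bead per cell per leaflet at cell centres —
  so the height-field estimator can be checked for exact recovery.
- **Brownian lipids**: 2-D Gaussian increments with per-axis variance 2·D·dt,
  wrapped into the box; the true unwrapped paths are stored for the unwrap
  oracle. Default D = 50 μm² s⁻¹, in the range measured for short-chain
  lipid bilayers.
- **Umbrella windows**: i.i.d. samples drawn exactly (inverse CDF on a 0.01 Å
  grid, cell-edge CDF so the sampler is unbiased — a half-cell shift tilts
  stiff-spring profiles measurably) from exp(−[U(z)+½k(z−c)²]). Profile
  families: harmonic; double-well as two Gaussian wells sunk in a flat
  plateau (bounded slopes keep every window resolvable, and the barrier scale
  matches lipid-extraction PMFs, ~5–11 k_BT); piecewise-linear.
- **Tubulation movie**: kinematic. A jittered square lattice holds the annular
  base plus one "reservoir" slot per future tube bead; shaft beads occupy a
  fixed cylindrical lattice (spacing matched self-consistently to the base
  lattice constant) and extrude as the scripted tip height L(t) grows at
  rate_pre (default 8.75 Å/ns, reaching 700 Å at the 80 ns severance); the
  neck is a waist 50 Å above the base following the neck schedule; at fission
  the head detaches, translating at rate_post, and neck beads retract into
  the base. The lattice construction (rather than Poisson placement) keeps
  the intact membrane a single cluster under the 1.5×NN cutoff: random
  placement leaves ~20% of points isolated at that cutoff. Keep the base
  population ≳3× the shaft population so the drained lattice stays above its
  site-percolation threshold; bead noise is 0.5 Å by default for the same
  reason.

What the fixtures deliberately do not emulate: bead-level force-field physics,
thermostat/barostat artefacts, autocorrelated umbrella sampling, lipid
exchange between leaflets, and solvent. Passing recovery tests therefore
demonstrates estimator correctness on data obeying the stated models, not
robustness to every artefact of real trajectories.

## Pipeline

`RunConfig` (YAML-serialisable, round-trip identical) names stages, per-stage
parameters, a seed and a replica count. Each stage regenerates its condition
per replica (seeds derived by hashing seed:stage:replica, kept below 2³¹),
analyses it, and flags whether the generator's truth was recovered; pooled
results are mean ± SE over replica means. The JSON summary embeds every
parameter actually used, the config hash and package version.
`compare_conditions` tabulates pooled observables across labelled conditions
and evaluates all pairwise orderings, so qualitative contrasts (thinner /
faster-diffusing / softer for shorter chains) can be read off directly.

## Known limitations

- Thickness, height field and spectrum assume a membrane normal along z and a
  square in-plane box for the spectrum.
- The MSD fit stderr understates the true error (correlated lags); use
  replicas for honest uncertainty.
- Histogram WHAM at bins comparable to the window width is biased; the
  internal fine grid removes this, but extremely stiff restraints (σ ≪ 0.05 Å)
  would need a smaller quadrature width.
- Topological fission detection requires the fixture/data bead spacing to be
  commensurate with the clustering cutoff; wildly inhomogeneous densities
  (e.g. a condensed droplet plus sparse membrane) distort the auto cutoff.
- `neck_profile` assumes a single tube along +z above the base membrane.
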