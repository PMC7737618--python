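# Methods

This note records the models implemented, the defaults that matter, the
numerical choices, and what the synthetic-data generators do and do not
emulate.

## Structural containers and IO

All stages operate on two containers: `AtomModel` (every atom of one model,
identity as parallel arrays) and `CalphaModel` (one Cα row per residue,
ordering stable: chains in file order, ascending author residue number
within a chain). Reading goes through gemmi; author numbering is never
rewritten, insertion codes are carried next to the residue number, and
alternate locations are resolved at read time to the highest-occupancy
conformer with ties broken by altloc letter — a deterministic, conventional
rule. Multi-model PDB is the trajectory/pathway output format; residue
numbers above 9999 use the hybrid-36 convention and coordinates round-trip
to the 0.001 Å precision of the PDB fixed columns.

Domain definitions (YAML) name residue sets per chain — at minimum
`dimer_domain` (static scaffold), `core_domain` (mobile transport domain)
and `binding_site` — plus a membrane normal. The normal defaults to +z of
the coordinate frame, the convention of membrane-aligned depositions and of
the synthetic generator; it is configurable because nothing in a coordinate
file defines it intrinsically. Residue correspondences across structures
are *inputs* (a TSV with one column per structure): curating a conserved
core across distant homologues involves structural-alignment and
gap-rebuilding choices outside this package's scope.

## Ensemble PCA

Structures matched through the correspondence are superposed onto a chosen
reference over a fit mask (typically the dimerization domain) with a
single-pass Kabsch fit — no iterative mean refitting, matching the
analysis convention of aligning everything to the reference scaffold. The
3M×3M coordinate covariance is diagonalized via SVD of the centered N×3M
matrix with population (1/N) normalization; variance *fractions*, the
reported quantity, are invariant to the 1/N-vs-1/(N−1) choice. At most
N−1 eigenvalues are nonzero.

Projections follow p(i,k) = T(i−0)·PC_k with T(i−0) the 3M difference
vector to the reference structure; the reference projects to zero on every
axis by construction. Eigenvector signs are fixed by making the
largest-magnitude component positive, or — the physically meaningful
convention — by `calibrate_signs`, which pins a designated outward-facing
structure to a positive PC1 so projections increase inward→outward.
Degenerate eigenvalue pairs keep their numeric order. PCA is Cα-only: the
elastic-network stage is Cα by definition and a mixed-atom conserved core
is not well defined across distant homologues; a heavier-atom PCA would
require correspondences at atom rather than residue granularity.

## Elastic network models

`cutoff-ANM`: spring k0 between every Cα pair within R_c (defaults
R_c = 12 Å, k0 = 1, the classic anisotropic-network parameterization). The
Hessian super-element of spring (i,j) is −(k/r⁰²)(d⊗d); diagonal blocks
close each row to zero, encoding exact translation invariance. `ED-ENM`:
sequence-local springs C_seq/s^e for separation s ≤ 3 within a chain and
nonlocal springs (C_cart/r)^p inside the cutoff; the defaults
(C_seq = 60, e = 2, C_cart = 6 Å, p = 6) follow the published MD-fitted
parameterization and are all configuration values. Every unit, property
and acceptance test runs on the fully specified cutoff-ANM so correctness
is never entangled with literature constants.

Rigid-body modes are identified as the 6 smallest eigenvalues (5 for
collinear node sets) when separated from the spectrum by a 10⁶ gap;
otherwise the rigid subspace (translations plus infinitesimal rotations,
orthonormalized) is projected out explicitly before rediagonalizing — the
robust path for near-degenerate toys. More near-zero modes than rigid-body
degrees of freedom raise a connectivity error naming the components: this
catches both disconnected graphs and genuinely floppy mechanisms (e.g. two
bundles joined only by parallel springs), which are modelling errors, not
numerical noise.

Fluctuations are MSF_i ∝ Σ_m ‖v_{m,i}‖²/λ_m over the first K modes
(default 20), in relative units — hinge *localization*, not absolute
amplitudes, is the use case. Hinges are local minima of the 5-residue
smoothed profile below the 25th percentile; both parameters are exposed
because no sharper operational definition exists.

## Transition pathways

`generate_pathway` iterates: compute modes at the current frame (a frozen
initial-mode option exists for cheap tests), rank the pool (default 20) by
|overlap| with the remaining direction (difference to the target, or a
supplied PC1 axis with a target amplitude), combine the top 3 with signed
overlap weights, displace by a fixed 0.5 Å rmsd step, then restore each
successive Cα–Cα virtual bond to its start-structure length in one N→C
pass per chain — keeping the trace physical at Cα resolution without any
all-atom rebuilding. The defaults (pool 20, 3 modes/step) reflect the
observation that elevator-like motions live in the low/mid-frequency
modes.

Two amendments proved necessary and are deliberate design choices. First,
after every step the frame is superposed back onto the start over the fit
mask (the scaffold, when a domain definition is available), so progress is
monitored in the dimerization-domain frame. Second, the rigid-body
component of the remaining direction is projected out before overlaps are
computed: internal modes cannot produce net translation or rotation, and
without the projection the walk stalls against an unreachable component —
observed directly on the toy system, where coverage plateaued at ~0.36
while the (frame-corrected) elevator shift was already complete. The step
amplitude is clamped to the remaining distance, so the walk cannot
overshoot; stalls (best overlap below 0.05) terminate explicitly with a
diagnostic, never silently. The generator contains no randomness:
identical inputs give bitwise-identical step logs.

Coverage is primarily the PC1 projection ratio p(model)/p(target) with the
start as reference; an rmsd-based alternative
1 − rmsd(model,target)/rmsd(start,target) is selectable because "fraction
of a transition" admits both readings and they differ off the straight
path. The elevator shift superposes state B onto state A over the
dimerization domain and splits the binding-site centroid displacement into
its membrane-normal magnitude and the in-plane remainder. The binding-site
membership is configuration; for the real exchanger fold the natural
default is the two conserved aspartates of the site.

## Surface areas and contacts

SASA uses the Shrake–Rupley rolling-probe algorithm (probe 1.4 Å, 960
Fibonacci points/atom — deterministic, ~1% accurate on an isolated sphere)
with one documented vdW table: C 1.70, N 1.55, O 1.52, S 1.80, P 1.80,
H 1.20 Å; hydrogens participate only if present; unknown elements require
an explicit radius override. Buried area follows the interface convention
(half-sum), the quantity interface servers report; a total-buried factor
of 1 is available. Because published interface numbers come from servers
whose exact radii/sampling are not reproducible, agreement is expected at
the ±15% level, not bit-exactly.

Contacts: residue pairs across the core/dimer domain boundary with minimum
heavy-atom distance ≤ 4.5 Å, kept only when both conservation grades
(1–9, ConSurf-style, supplied as CSV) reach the floor of 8; unscored
residues get grade 0 and drop out. Gate extraction intersects the contact
participants with a hydrophobic residue-name set
{ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO} and splits them by side of the
binding-site centroid along the membrane normal — the candidate seals
above and below the ion site. Cutoff and floor are configuration: the
underlying analyses never published a distance criterion.

## Trajectory binding and densities

Orthorhombic periodic boxes only (the simulated systems are orthorhombic);
triclinic cells are rejected loudly rather than silently mis-wrapped. Ion
site distances are minimum-image; binding is distance ≤ 3 Å to any site
atom (the Na⁺–carboxyl-oxygen convention), occupancy is the fraction of
frames with ≥1 bound ion, and bound events are contiguous segments with
entry/exit frames. Densities histogram wrapped coordinates on a regular
grid (half-open voxels: a boundary coordinate belongs to the higher-index
voxel), average over frames, and convert to mol/L by
c = ⟨count⟩/(V_voxel·10⁻²⁷·N_A); total average count is conserved under
re-binning to 10⁻⁹ relative. Grids export to OpenDX. Coordinates are used
as given — per-frame rotational superposition before density accumulation
is a known artefact source (it smears the membrane into a circular patch)
and is therefore off by default.

## Assay fits

The dequench percentage condenses a fluorescence trace via its 3/4/5-minute
reads. Two formulas ship: the literal protocol form
(FI₄−FI₃)/(FI₅/FI₃)·100, which divides by a dimensionless ratio and can
exceed 100 severalfold, and the span-normalized form
(FI₄−FI₃)/(FI₅−FI₃)·100 — the fraction of the collapsible gradient
dissipated by substrate. Span-normalized is the default; the literal form
is retained for exact reproduction rather than second-guessing the
protocol's intent.

Michaelis–Menten and 4PL fits use Levenberg–Marquardt with documented
initializations (V_max⁰ = max response, K_M⁰ = concentration nearest
half-max; plateaus from the curve ends, T_m⁰ at the half-signal crossing,
slope sign from the trend). The 4PL is parameterized on linear temperature,
y = d + (a−d)/(1+(T/T_m)^b), with T_m the inflection; commercial software's
exact variant is not re-derivable, so validation is by recovery on
synthetic curves rather than output matching. Fits must improve on their
initialization (descent is asserted), T_m must lie inside the measured
range, and flat data raise errors instead of returning garbage.
ΔT_m = T_m(condition) − T_m(control).

## Synthetic data: what it emulates, and what it does not

The toy elevator builds each domain from ideal Cα helices (rise 1.5 Å,
radius 2.3 Å, 100°/residue — successive Cα–Cα ≈ 3.83 Å), each helix its
own chain, domains facing each other across x = ±6 Å; state B moves the
core rigidly by d Å along +z (optionally rotated about the normal), with
the scaffold bitwise identical. The ±6 Å spacing makes inter-domain
springs brace the sliding direction — at wider separations the cutoff-ANM
network acquires a genuine floppy mechanism and the mode computation
(correctly) refuses it. Domains with more than two helices use a
two-column grid, so a four-helix scaffold is mutually braced and
fluctuation profiles show the expected mobile-core/rigid-scaffold
contrast.

Ensembles add isotropic Gaussian coordinate noise to each state. Ion
trajectories place round(c·N_A·V) ideal-gas ions uniformly per frame
(150 mM in (100 Å)³ gives 90 ions); when a binding site is requested, four
static site atoms surround it, one tagged ion is placed inside the
threshold for a contiguous block of frames covering the programmed bound
fraction, and bulk ions are resampled out of an exclusion shell
(threshold + 0.5 Å) so the programmed fraction is the *exact* occupancy
ground truth. Dose–response data are Michaelis–Menten evaluations with
multiplicative Gaussian noise; melting curves are 4PL evaluations with
Gaussian noise scaled by the transition span (strictly multiplicative
noise would vanish at a zero plateau and flatter the fit).

Every generator is a pure function of (parameters, seed) on a local
`numpy` Generator — no global random state.

What passing tests show — and don't. The generators reproduce the *data
shapes and the stated study conditions* (two-state architecture, noise
levels, salt concentration, kinetic constants, melting shift), so recovery
tests demonstrate that the estimators are unbiased and correctly
implemented at those conditions. They do not emulate correlated
experimental error, anisotropic coordinate uncertainty, partial occupancy,
ion–ion interactions, membrane anisotropy, or model bias in real
deposited coordinates; quantitative agreement on real structures
additionally depends on the curated correspondence and domain definitions
supplied by the user.

## Problem sizes and reproducibility

Default test and acceptance problem sizes — 120-residue toys, 6–8-member
ensembles, 500-frame/90-ion trajectories, 200 kinetic and 50 melting
replicates — were chosen as the smallest sizes at which the statistical
acceptance bands are comfortably resolved; everything is pure Python/numpy
and completes in seconds on one CPU. The demo workflow
(simulate → pca → enm → pathway → shift) is byte-reproducible under a
fixed seed, and `scripts/acceptance.py` derives every stream from its
`--seed` argument.

## Known limitations

Cα-only resolution throughout the structural stages (no side-chain
repacking along pathways); single-pass bond re-idealization can leave
small residual bond-length error after large steps (bounded by the 0.5 Å
step amplitude); cutoff-ANM spring constants are unitless, so mode
eigenvalues are relative stiffnesses, not frequencies; SASA accuracy is
bounded by the point density (~1% at 960 points); densities assume
orthorhombic cells; the 4PL temperature parameterization differs from
ratio-of-logs variants by a reparameterization of the slope, so slopes —
not T_m values — may differ from other software.
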