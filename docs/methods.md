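# Methods

This note records the models implemented, the conventions and defaults
chosen where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Ring puckering

A six-membered ring's out-of-plane geometry is reduced to the
Cremer–Pople triple (Q, θ, φ): the mean plane is defined so the six signed
displacements z_j sum to zero; the Fourier components give
q₂ (equatorial), q₃ (chair), Q² = q₂² + q₃², tan θ = q₂/q₃. With the ring
ordered O5, C1, …, C5 (the package convention, asserted by tests), the
⁴C₁ chair of D-pyranoses sits at θ = 0 and ¹C₄ at θ = 180°. Starting the
ring k atoms later rotates φ by 120°·k and mirrors θ for odd k, which is
why the convention is pinned rather than arbitrary.

The inverse construction places the exact CP displacements on a regular
hexagonal projection; the round trip is exact to ~1e-13 over the whole
sphere, which is the oracle used throughout. Rings with Q < 1e-6 Å are
reported planar with θ = φ = 0 and an explicit flag rather than NaN.

Conformer classification uses the 38 canonical forms: chairs at the
poles, boats/twist-boats at θ = 90° every 30° of φ (the standard
equatorial itinerary O,3B, ³S₁, B1,4, ⁵S₁, …), and envelopes/half-chairs
on the tropics at θ = arctan √2 ≈ 54.7°. The tropic and boat names are
derived algorithmically from the displacement sign patterns and verified
self-consistent by a test; the twist-boat names are pinned to the standard
itinerary. θ within 45° of a pole is classified as the corresponding
chair; this threshold is an argument.

## Crystal contacts and packing

Symmetry expansion applies every operator and the lattice translations
needed to cover a requested radius (closed ball; per-axis translation
ranges derived from the cell's perpendicular widths). A brute-force
5³-supercell enumeration is the test oracle.

Hydrogen bonds are geometric: donor O/N/C carrying an H, acceptor O/N or
halogen, d(D···A) ≤ 3.6 Å (3.9 Å for Cl/Br/I acceptors), D−H···A ≥ 120°,
all configurable. These defaults cover the full range of O−H···O,
C−H···O and O/C−H···halogen interactions reported for this compound
family (up to ~3.5 Å for C−H···O, ~3.3 Å for O−H···Cl) without flooding
the output; they are a documented substitute for the (unpublished) exact
defaults of interactive tools. Duplicates are avoided by keeping donors
in the asymmetric unit, which selects exactly one representative per
symmetry orbit of each contact.

The packing index is Z·V_vdW/V_cell with V_vdW the voxelized union of
Bondi spheres of the asymmetric unit (overlaps counted once); voxel
default 0.1 Å, validated to 1% against the analytic sphere volume and a
10⁶-point Monte-Carlo union oracle.

X−H normalization moves each hydrogen along its existing bond vector to
the neutron-diffraction distance (C−H 1.083 Å, O−H 0.983 Å, N−H
1.009 Å), because X-ray refinement systematically shortens X−H bonds
(≈0.97 vs 1.09 Å for C−H). It is on by default for Hirshfeld analysis and
off for reporting refined geometry. Orphan hydrogens are flagged and left
in place.

## Spherical atomic densities and Hirshfeld surfaces

The free-atom densities are a self-contained single-zeta Slater-type
orbital model: for each occupied shell group, ρ_shell(r) =
occ · |R_n*(r)|²/4π with R a normalized STO whose exponent comes from
Slater's screening rules (effective principal quantum numbers 1, 2, 3,
3.7, 4.0). Each atom therefore integrates to its electron count exactly
(analytically), is everywhere positive, and is numerically monotone
beyond ~0.35 Å for H, C, N, O, F, P, S, Cl, Br and I. A fitted
pure-exponential-sum representation was rejected: sums of decaying
exponentials are completely monotone and cannot represent shell
structure (local errors near 80%). The STO model is coarser than
Hartree–Fock tabulations, so absolute fingerprint positions differ
slightly from tools built on HF densities; all package tests are
self-consistent against this model.

The surface is the marching-cubes 0.5 isosurface of
w = ρ_pro/(ρ_pro + ρ_env) on a regular grid (default 0.15 Å spacing, 3 Å
padding, environment = all symmetry images within 6 Å of the central
molecule). Meshes are checked watertight; open results raise a
resolution error unless an open patch is explicitly requested (the
two-atom bisecting-plane fixture is such a patch). Per-vertex d_i/d_e and
nearest-atom elements come from KD-trees; contact contributions are
tallied per triangle at the centroid, which makes the independent
re-tally in the tests exact.

Interpolated w at extracted vertices stays within 0.40–0.60 with median
0.5 at the default grid. Summed molecular Hirshfeld volumes tile ~96% of
the cell on the dense single-atom toy crystal: the deficit is real
physics (interstitial points where no molecule holds a majority of the
density), not discretization, and it shrinks as packing loosens; the 5%
partition test bound reflects this.

Enrichment uses R_XY = 2 S_X S_Y off-diagonal and R_XX = S_X² (the
standard convention; the source literature prints only the off-diagonal
case). Ratios with R below a configurable floor (1e-4) are reported
missing rather than as huge numbers. Contact typing is by element only
(all H equivalent). Fingerprints are area-weighted 2-D histograms, 0.01 Å
bins over 0.4–3.0 Å by default, with out-of-range points clamped into the
edge bins so the histogram always totals 100%.

## NMR conformational analysis

The Karplus model is the six-term Fourier form ³J(φ) = C₀ + C₁cos φ +
C₂cos 2φ + C₃cos 3φ + S₁sin φ + S₂sin 2φ. Coefficients may be supplied
directly or derived from the Haasnoot–Altona equation
(P₁…P₆ = 13.70, −0.73, 0, 0.56, −2.47, 16.9; λ = Huggins
electronegativity of the substituent's α atom minus hydrogen's, shipped
as an editable table with OH = 1.40). The HA curve is an exact member of
the Fourier family (cos² terms fold into cos 2φ/sin 2φ with C₃ = 0), so
the projection is closed-form, not a fit — a test checks exactness to
1e-10 across φ.

Inversion scans at 0.1° and refines each bracketed root with Brent's
method; all roots are returned sorted. Choosing the chemically relevant
root (e.g. the one compatible with a ⁴C₁ ring) is deliberately a
separate, explicit step because Karplus curves are multi-valued.

Rotamer populations: the gt/gg/tg system is the fixed, nonsingular 3×3
linear system of the limiting couplings with the closure row; the raw
solution is always reported, and when it leaves [0, 1] a non-negative
least-squares solution on the simplex is reported alongside
(`constrained=True`) — never a silent clip. The C6–O6 gauche/trans split
solves J_app = D·J_gauche + E·J_trans with D + E = 1; the difference
J_gauche − J_trans = 3(A+B) + 20C is strictly positive on the simplex, so
the split is always well conditioned for valid fractions. Geminal
couplings are handled as magnitudes (they are negative physically; the
limiting values are quoted as magnitudes). The apparent geminal relation
is implemented as the population average of the gauche/trans limiting
values; the source's rendering of that equation mixes ³J symbols into a
²J relation, treated here as a typo.

NOE rates are ordinary least-squares slopes of intensity vs mixing time
over all supplied points (≥3; default schedule 100–750 ms), optionally
restricted to an initial-buildup cutoff to guard against spin diffusion;
distances follow r = r_ref(σ/σ_ref)^(−1/6) with r_ref = 1.77 Å for the
geminal H6R–H6S reference pair.

## Ligand environment and electrostatics

Binding sites collect residues with any atom within a cutoff (default
4.5 Å) of the ligand, sorted by closest approach; waters participate only
if kept at parsing time. Ligand fingerprints reuse the Hirshfeld
machinery with the ligand as promolecule and the pocket as environment
(nitrogen enters the contact alphabet naturally).

The electrostatic model is point multipoles: charge–charge,
charge–dipole, dipole–dipole and charge–quadrupole (Buckingham
convention, traceless) terms, Coulomb constant 1389.35458
kJ·mol⁻¹·Å·e⁻²; higher-order terms are neglected. Every pair is booked
against the 4.5 Å near/far boundary. Moments are user-supplied (any
population analysis); full aspherical pseudoatom databanks are not
redistributable, so published per-residue energies from such treatments
are reproducible only qualitatively — this is a documented scope
boundary, not an approximation claim. Formal charges for Arg/Lys/Asp/Glu
(±1) are provided as a convention constant for building charge models.
Protein chains are analysed separately.

## Synthetic data: what it shows and what it does not

All generators flow from explicit `numpy.random.default_rng(seed)`
streams; identical seeds give bit-identical outputs, and every planted
truth is recovered exactly by the corresponding analysis in the
noiseless limit (tested). Default noise: Gaussian SD 0.2 Hz on couplings
and 2% of maximum intensity on NOESY points — plausible stand-ins for
line-fitting precision. The toy crystals are small rigid molecules at a
fixed general position; they exercise symmetry, contact search, packing
and surface partitioning, but contain no conformational disorder, no
thermal motion, no solvate chemistry and no realistic molecular shapes,
so passing tests validate the algorithms, not any claim about real
crystal-structure energetics. Stochastic recovery checks use 500
repetitions (rotamers, unbiased within 0.01) and 200 repetitions (NOE
distance at 2.5 Å, RMSE < 0.05 Å) at fixed seeds; problem sizes
(grids 0.1–0.15 Å, toy cells of a few Å, 10⁵–10⁶-point Monte-Carlo
oracles) were chosen as the smallest at which the checked quantities are
converged.

## Known limitations

* Quantities tied to the deposited experimental structures (the 7.8°
  chair deviation of the 2-chloro glucose analogue, packing indices near
  70%, O···H ≈ 37.5% contact shares, E_OH > 1) need the CCDC/PDB
  depositions and are not recomputed offline; agreement is expected only
  to ~1 percentage point given unstated grid settings in the original
  surface computations.
* Periodic DFT cohesive energies and aspherical-pseudoatom electrostatic
  energies are out of scope by design.
* Five-membered-ring pseudorotation, d_norm surface aesthetics,
  relaxation-matrix NOE analysis and spectral processing are not
  implemented.
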