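# Methods

`c60kit` re-implements, at desk scale, the computational analyses behind a
protein-directed fullerene (C60) co-assembly study: the alchemical
double-decoupling estimate of the fullerene's affinity for its
protein-surface binding site, the sedimentation-equilibrium evidence for a
tetramer–octamer self-association in solution, the crystal-lattice and
backbone-motif geometry analyses, and the Beer–Lambert / SEC solution
quantification. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic test systems do and
do not establish.

## 1. Fullerene and crystal geometry

**C60 builder.** The molecule is built as a truncated icosahedron with a
single uniform bond length (default 1.4392 Å, the experimental average
carbon–carbon distance). The canonical vertex table (cyclic permutations
of (0, ±1, ±3φ), (±1, ±(2+φ), ±2φ), (±2, ±(1+2φ), ±φ), φ the golden
ratio) has edge length 2 and is rescaled by `bond_length / 2`. Edges are
the 90 nearest-neighbour pairs; faces are recovered by merging coplanar
convex-hull triangles, giving the 12 pentagons and 20 hexagons. The real
molecule's slight 6:6 versus 6:5 bond alternation is deliberately not
modelled — a uniform-bond geometry is what the force-field atom type
implies. Closed-form checks: circumradius `(a/4)·√(58+18√5)` and Euler
characteristic V−E+F = 2.

**Lattice expansion.** A crystal is expanded into its identity unit plus
every symmetry/translation image with at least `min_atoms` atoms (default
3) within `cutoff` (default 16 Å) of the initial unit. Space-group
operators come from gemmi's canonical tables (any Hermann–Mauguin symbol,
not just the two groups the fixtures use). The integer-translation search
range is derived per axis from the fractional bounding boxes of the unit
and each operator image plus the cutoff converted to fractional units via
the row norms of the deorthogonalisation matrix — an upper bound, so no
qualifying image can be missed; a Cartesian bounding-box prefilter then
discards non-candidates cheaply. Equivalence with brute-force operator ×
translation enumeration is a test invariant.

**Superposition.** Kabsch least-squares superposition via SVD with the
determinant correction (always a proper rotation). The motif search uses
the same decomposition internally; near-zero RMSDs are computed through
the explicit rotation residual rather than the singular-value identity,
which loses half the significant digits to cancellation.

**Matthews arithmetic.** V_M = cell volume / (Z × ASU mass) with Z the
space-group operator count, and solvent fraction 1 − 1.23/V_M clamped to
[0, 1). The constant 1.23 Å³/Da is the conventional inverse protein
density (partial specific volume ≈ 0.74 mL/g). The ASU mass is the
protein mass by convention; whether a bound ligand is counted is the
caller's choice (pass protein+ligand mass to include it).

## 2. Motif search

The binding-site query is an ordered list of disjoint backbone segments
(N, CA, C, O per residue; the full site is residues 2–9 on one chain pair
and 19–24 on the opposing pair, 112 atoms). The search enumerates every
combination of contiguous backbone-complete runs — any chain assignment
consistent with the segment lengths, placements non-overlapping — and
keeps combinations whose full-backbone optimal-superposition RMSD is at
or below the cutoff (1.9 Å in the published census).

Enumeration is depth-first with an exact early-abort bound: the optimal
RMSD over a subset of atoms, scaled by √(n_subset/n_total), is a lower
bound on the full-motif RMSD (the full superposition evaluated on the
subset can only be worse than the subset's own optimum, and the full mean
square is at least the subset share of it). Pruning on this bound
discards no true match; brute-force equivalence on small databases is a
test invariant. Symmetric duplicate placements — the same set of runs
matched in a different segment order, possible because the site is
two-fold symmetric — collapse to a canonical key (placements sorted
within equal-length groups), keeping the lowest-RMSD representative.
Ties are broken by (target id, placements) lexicographic order.

Match deduplication keeps the best match per concatenated sequence;
sequence logos are per-position frequency tables over deduplicated
matches within an RMSD threshold (default 0.3 Å). Reproducing the
PDB-wide census (180 instances / 21 lattices) is out of scope: it is a
property of a dated database snapshot, not of the algorithm.

## 3. Toy particle engine

A minimal Lennard-Jones + harmonic-restraint engine supplies ensembles to
the free-energy machinery. Units: kcal/mol, Å, K.

* LJ in (ε, r_min) form, U = ε[(r_min/r)¹² − 2(r_min/r)⁶];
  Lorentz–Berthelot mixing (arithmetic r_min, geometric ε); cutoff 10 Å
  with a CHARMM-style polynomial energy switch starting at 6 Å.
* Soft core: a pair at coupling scale s has its squared distance shifted
  by `shift_coeff·(1−s)` inside the kernel and its energy scaled by s.
  The shift coefficient is 8 Å² in first (swap) steps and 20 Å² in second
  (dummy-decoupling) steps. At s = 1 the plain potential is recovered
  exactly; energies are continuous in λ.
* Alchemical assignments are signed: +1 particles scale with the coupling
  strength λ, −1 particles with 1−λ (the dual-topology partner appearing
  as the ligand vanishes). Opposite-sign pairs are excluded — they occupy
  the same site; same-sign pairs interact at full strength.
* Harmonic terms are (k/2)(d−r0)², for bonds and for atom–atom or
  centroid–centroid restraints; λ-coupled restraints take their force
  constant from the caller's schedule, and only λ-dependent terms enter
  perturbation energies.
* Sampling is single-particle-move Metropolis Monte Carlo in NVT.
  A Monte Carlo sampler was chosen over molecular dynamics because its
  stationary distribution is exact and directly verifiable (equipartition,
  double-well occupancies, Boltzmann quadrature); pressure coupling is
  irrelevant for the analytic test systems. Trajectories are deterministic
  given a seed. No electrostatics: the decoupled species in the cycle are
  uncharged moieties, and the toy systems exercise the vdW path only.
  The long-range analytic vdW tail correction is omitted (cutoff-switched
  energies only); all quantitative checks are internal-consistency or
  analytic comparisons for which this is immaterial.

The per-move inner loop runs on plain floats with precomputed pair lists
(numpy array overhead dominates at these particle counts); the full
energy breakdown uses a vectorised pair table. Both paths are compared in
tests.

## 4. Double-decoupling free energies

**Estimator.** Zwanzig exponential averaging per window,
ΔG = −RT ln⟨exp(−ΔU/RT)⟩, computed with log-sum-exp; a Bennett
acceptance-ratio estimator is provided as an optional cross-check, not
used by any headline number.

**Cycle.** The binding free energy is assembled from two transformations,
each in two steps, with a single-atom dummy intermediate (vdW radius
4.5 Å, well depth 1 kcal/mol) that keeps the path reversible: step 1
swaps the ligand out while the dummy appears in the site; step 2
decouples the dummy (the ligand, fully decoupled and tethered to the
dummy, contributes nothing and is omitted from step-2 systems).
Transformation 1 runs in the bound complex, transformation 2 in bulk;
the dummy's gas-phase contribution cancels between end states, and the
site restraints on the dummy (constant k, not λ-coupled) cancel within
each transformation. Then

dG_bind = ΔG(transformation 2) − ΔG(transformation 1) − RT ln(c°·V_k),

with V_k = (2πRT/k)^{3/2} the configurational volume of the
ligand–dummy restraint at its decoupled-state force constant
(k = 10 kcal/mol/Å²) and c° the standard concentration expressed in
molecules/Å³. The sign of the correction is fixed by the toy host–guest
self-consistency oracle (below), not by convention; the k-dependence of
ΔG(transformation 1) and of the correction cancel exactly, which the
same oracle exercises. Kd = c°·exp(dG_bind/RT).

**Restraint schedule.** The ligand–dummy restraint rises from 0 to
10 kcal/mol/Å² along the decoupling path. The default schedule is linear
in λ (endpoints are all that affect the physics; the shape affects only
variance) and the form is pluggable. The host–guest fixture uses a cubic
schedule k(λ) = 10λ³: the free energy of harmonic confinement scales as
−(3/2)RT ln k, so near-geometric spacing of k equalises window overlaps,
whereas a linear schedule concentrates the entire confinement cost in the
first window and biases exponential averaging noticeably.

**Directions, replicates, errors.** Each step can run forward
(decoupling 0→1) or reverse; reverse cumulative values are negated on
reporting so all results share the decoupling convention. Step means pool
both directions across replicates; the cycle's standard error is the
quadrature sum of step-level standard errors of the mean. A hysteresis
report flags steps whose forward/negated-reverse discrepancy exceeds
twice the combined standard error. Window lengths default to 1,000
equilibration + 19,000 collection sweeps (mirroring the 10/190 ps ratio
of the original protocol); the test suite uses 30 windows ×
(2,000 + 10,000) sweeps and 3 replicates per direction, sizes chosen so
the statistical errors line up with the oracle comparison.

**Importance reweighting.** For runs carried out under an extra constant
bias restraint (as used for single-aromatic-group affinities), the
unbiased expectation is ⟨A·e^{+U_b/RT}⟩/⟨e^{+U_b/RT}⟩, log-sum-exp
stabilised.

## 5. Toy systems and their ground truths

* **harmonic** — one particle in a λ-scaled harmonic well inside a
  periodic box (edge 8 Å). Decoupling ΔG is analytic:
  −RT ln(V_box/V_well) with the erf-truncated Gaussian volume. The
  fixture's k(λ) mapping is quadratic, for the same overlap reason as
  above.
* **lj-solute** — one solute in a 40-particle weak LJ solvent (box 22 Å),
  providing the bulk-phase (transformation 2) machinery: ligand→dummy
  swap, then dummy decoupling. No closed form; used for reversibility and
  hysteresis checks.
* **host-guest** — a pocket of three fixed host atoms on an equilateral
  triangle (circumradius 6.5 Å) whose pair minima all coincide at the
  centroid, giving a unique binding site of depth 3·ε_pair
  (≈ −5.1 kcal/mol) for a single-particle ligand in a 34 Å box, in
  vacuum. The dummy is restrained to the host centroid (k = 10, r0 = 0),
  mirroring the three-site-atom restraint of the original protocol. The
  pocket depth is chosen so that the bound region dominates the
  configurational integral (bound fraction ≈ 0.8): the unbound volume,
  whose slow box-scale diffusion is the sampler's weak point, then
  contributes little to the estimate. Ground truths: (i) direct
  bound-fraction counting from one long unrestrained run — the ligand–
  host interaction is identically zero beyond circumradius + cutoff
  (16.5 Å), so Z = V_unbound/(1−f) exactly, with block-averaged errors;
  (ii) deterministic 3-D grid quadrature of ∫exp(−U/RT)d³r. The cycle,
  the occupancy oracle and the quadrature agree within combined
  statistical error (≈ −2.4 kcal/mol for the default design). Vacuum
  (no explicit solvent) keeps the occupancy oracle's constant-potential-
  outside-the-site assumption exact; the lj-solute fixture covers the
  solvated machinery separately.

The toy cycle establishes the correctness of the machinery — estimator,
restraint bookkeeping, standard-state correction, error propagation. It
does not reproduce the published protein–fullerene number (−9.8 ± 0.3
kcal/mol) or the single-aromatic-group values: those require
explicit-solvent, cluster-scale simulation (a 336 ns campaign, whose size
the protocol-arithmetic helper reproduces exactly from the stated
window/replicate scheme).

## 6. Sedimentation equilibrium

Each species follows c(r) = c_ref·exp[σ(r²−r_ref²)] with
σ = M(1−v̄ρ)ω²/(2RT) in cm⁻² (CGS gas constant). For the
tetramer↔octamer scheme (Kd = [tet]²/[oct], molar), the octamer profile
is linked by mass action at the reference radius and carries σ_oct =
2σ_tet — exact when the octamer mass is twice the tetramer mass and v̄ is
shared, so the link c_oct(r) = c_tet(r)²/Kd holds at every radius. That
radial-link constancy is the generator's defining invariant and is what
makes a global multi-speed fit identifiable.

The global fit is nonlinear least squares (scipy `least_squares`,
Levenberg–Marquardt) over all scans simultaneously: shared log₁₀Kd (and
optionally the molar mass, fitted by default only for the single-species
template), per-scan log reference concentration and baseline. Parameter
standard errors come from the Jacobian at the solution. Model selection
accepts the two-species model only when it improves the global rms by
more than 10% with a finite Kd standard error — a concrete rule standing
in for "the best-fitting model was accepted".

Synthetic datasets default to the study conditions: Kd = 118 μM, tetramer
13.4 kDa, v̄ = 0.73 mL/g, ρ = 1.0 g/mL, speeds 25/30/35/40 k r.p.m.,
noise 0.005 AU. The remaining knobs — 4 μM loading at the meniscus,
extinctions 5,000/10,000 AU·cm⁻¹·M⁻¹, 1.2 cm optical path, 80 radii over
5.90–6.10 cm, 0.01 AU baselines — are conventional values for a
short-column equilibrium run designed to resolve a weak self-association:
the octamer contributes a few percent of the signal at the meniscus at
25 k r.p.m. and roughly half near the base at 40 k r.p.m. The fitted v̄
and buffer density are inputs, never fitted; for real data they must be
supplied, not inferred. No meniscus-depletion modelling; the fit uses the
provided radius window as-is.

## 7. Solution quantification

Beer–Lambert c = A/(εl) with the fullerene's 340 nm molar absorptivity
(49,000 M⁻¹cm⁻¹) as the canonical ε; stoichiometry is (monomer/n)/ligand,
e.g. 585 μM peptide as tetramers against 6.22 μM C60 gives ≈ 23.5 ≈ 24
tetramers per fullerene. SEC calibration is a least-squares line on
log₁₀(mass) vs elution volume over kit standards; queries outside the
calibrated range are answered but flagged. Peak calling on traces is
deliberately simple — moving-average smoothing (5 points) and local
maxima above 10% of the global maximum — and the octamer call is an
apparent-mass readout, not a hard classification.

## 8. Synthetic structures

Helix bundles are built from a one-time internal-coordinate (NeRF)
construction of an ideal α-helix (φ = −57°, ψ = −47°, ω = 180°; N–CA
1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; angles 111.2/116.2/121.7/
120.8°). Each backbone atom type's cylindrical parameters (radius, phase
offset from CA, axial offset) are extracted from that build and reused
parametrically, so a requested rise (default 1.5 Å) and residues-per-turn
(default 3.6) are honoured exactly at the CA level. Four copies are
placed antiparallel on a square (default half-diagonal 7.5 Å). These
fixtures have ideal geometry and poly-alanine sequences: passing motif
searches on them demonstrates algorithmic correctness (exhaustiveness,
RMSD bookkeeping, dedup), not performance on real, irregular backbones.

Motif planting rigidly superposes the whole query onto the chosen target
segments (one transform, preserving internal geometry), adds i.i.d.
Gaussian coordinate noise, overwrites the target backbone, and emits a
ground-truth record; the expected plant RMSD is ≈ σ√3 (three coordinates
per atom, minus a small superposition absorption).

Every generator draws from a named substream of the master seed
(`SeedSequence(seed, spawn_key=...)`), so generators are pure functions
of their config and adding one never perturbs another's output.

## 9. Known limitations

* The engine has no electrostatics, no angle/dihedral terms (C60 is
  treated as rigid where it appears as geometry), no barostat, and no
  water model; it is a verification harness, not a simulator of record.
* Zwanzig estimation is single-direction per run; bidirectional
  per-window acquisition (and BAR as the primary estimator) would reduce
  variance but is not what the reference protocol used.
* The occupancy oracle requires the ligand–host interaction to vanish
  outside a sphere that fits the periodic box; the host-guest box size
  (34 Å) is the smallest that satisfies this with the default pocket.
* Sedimentation fitting assumes ideal, non-interacting exponentials
  (no thermodynamic non-ideality, no meniscus artefacts).
* SEC calibration is log-linear over the kit range only; apparent masses
  of non-globular species are apparent, as on a real column.
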