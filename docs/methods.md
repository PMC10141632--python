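# Methods

## Scope and data model

The package analyses structure trajectories of two-domain (kinase /
pseudokinase) systems: ordered coordinate frames with strictly increasing
time stamps in ns, a shared atom table carrying identity (serial, name,
residue, chain, author residue number) and physical parameters (mass amu,
charge e, radius Å, Lennard-Jones well depth and Rmin/2).  Multi-model PDB
is the trajectory interchange format (MODEL/ENDMDL, frame times in
`REMARK 250` lines; files without times fall back to a configured save
interval); PQR (whitespace pdb2pqr dialect) carries charges and radii.
Selections are named chain + closed residue-number intervals in author
numbering, e.g. an N-lobe `T815-P906` and a C-lobe `S907-S1100`; the
optional residue-letter prefixes are validated against the structure when
it carries standard residue names and ignored on synthetic residues.

Charges and radii are assigned from a bundled parameter table keyed by
(residue, atom name).  The table is total over the synthetic residue set or
assignment fails listing every unmatched atom.  The phosphotyrosine
phosphate's protonation state (−1 vs −2 net) is a modelling choice the
table deliberately exposes as an explicit entry rather than defaulting.

## Cleft topology

The cleft size is the Euclidean distance between the *mass-weighted*
centers of the two lobe selections, per frame (a geometric-center mode
exists for sensitivity checks).  Window statistics use the half-open
window `(t_start, t_end]` with sample (n−1) SD: at 0.1 ns spacing a
70–100 ns window contains exactly the 300 frames at 70.1 … 100.0 ns,
which is the bookkeeping the windowed means assume.  RMSD stability checks
use Kabsch superposition (translation + proper rotation, via scipy's
quaternion solver); the suite cross-checks it against a direct SVD
implementation.

The separation protocol rigidly translates a mobile selection along the
unit vector from the fixed selection's mass center to the mobile's, by
10/15/20 Å or any non-negative displacement.  The displacement axis is not
uniquely determined by the physics; the mass-center connection line was
chosen because it is the same axis the force decomposition projects onto,
making "binding force" and "separation direction" commensurate.
Composition along the axis is exact (10 Å twice equals 20 Å once) and the
mobile selection's internal geometry is preserved to machine precision.

## Contacts and occupancy

Salt bridges: any basic nitrogen (Lys NZ; Arg NE/NH1/NH2; config-extensible)
within 4.0 Å of an acidic oxygen (Asp OD1/OD2, Glu OE1/OE2, nucleotide
phosphate oxygens, phosphotyrosine O1P–O3P), deduplicated to one record per
residue pair at the minimum atom distance.  Hydrogen bonds: donor heavy
atom N/O with a hydrogen bound within 1.25 Å, acceptor any other N/O,
donor–acceptor distance ≤ 3.5 Å, and the D–H vector within 20° of the D→A
direction, at atom-triple granularity.

Two conventions here are easy to get wrong and are therefore stated
prominently:

- the 20° cutoff is the *deviation from collinearity* of D–H versus D→A
  (the convention of the common visualization/analysis tools), not the
  D–H···A interior angle — the two classify differently;
- all cutoffs are boundary-inclusive: a pair at exactly 4.0 Å counts.

Occupancy is `100 × (frames where the criterion holds) / (all frames)` per
distinct pair; pairs never observed are omitted.  High-occupancy filtering
is strictly greater-than ("(>10%)" excludes 10.0).  Per-residue summed
occupancy adds a residue's pair occupancies and may exceed 100%; this is an
interpretation (a residue with two 60% bonds scores 120%), not a frame-wise
union, and is labelled as such in the API docs.

## Electrostatic forces

The production force path is the analytic screened-Coulomb (Yukawa) sum in
the solvent dielectric:

    F = Σ_ij k_e q_i q_j e^{−κr} (1 + κr) / (ε_w r²) r̂,
    k_e = 332.0637 kcal·Å/(mol·e²),

converted to kT/Å with kT at the medium temperature (0.6160 kcal/mol at
310 K).  κ comes from the 1:1 electrolyte via κ² = 8π·l_B·n; at the
defaults (80, 150 mM, 310 K) the Debye length is 8.09 Å (the familiar
7.9 Å figure corresponds to 298 K).  The analytic path was chosen for the
production statistic because it is oracle-exact and satisfies Newton's
third law bit-for-bit (pair terms are evaluated in a canonical direction
and negated, avoiding ulp-level asymmetry); the PB solver below provides
the two-dielectric fields the analytic route cannot, and the two must
agree in the homogeneous-medium limit, which the suite asserts.

Decomposition: with u the unit vector from the target's mass center toward
the source's, `F_binding = F·u` (positive = attraction),
`F_sliding = (|F|² − F_binding²)^½`, `α = arccos(F_binding/|F|)`.
Identities `binding = |F|cos α`, `sliding = |F|sin α`,
`binding² + sliding² = |F|²` hold to 1e−9 relative.  Frame averages carry
95% confidence intervals from the Student-t quantile on the per-frame
sample; a single-frame window is an error rather than a zero-width CI.

## Finite-difference linearized Poisson–Boltzmann

A 7-point finite-difference discretization of
`∇·(ε∇φ) − ε_w κ² λ(r) φ = −4π k_e ρ` on a cubic grid:

- box sized so the solute (atom spheres included) spans the filling ratio
  (default 0.70) of the edge, at the configured resolution (default
  2 grid/Å); a minimum extent can force a larger box for far-field reads;
- ε = ε_in inside any atom sphere, ε_out outside; edge dielectrics are
  harmonic means over 3 sub-samples per edge (series composition), which
  is what makes the Born energy accurate at 0.5 Å spacing;
- λ = 1 only at solvent nodes (no Stern layer in v1);
- charges spread trilinearly to the 8 surrounding nodes;
- Dirichlet boundary from the analytic Debye–Hückel superposition;
- the SPD system is solved by Jacobi-preconditioned conjugate gradients to
  1e−8 relative residual.

An all-zero charge vector short-circuits to the exact φ ≡ 0 solution.

Polar solvation is the reaction-field difference of two solves on the
*identical* grid and charge discretization — solvated (ε_in/ε_out, κ) minus
reference (homogeneous ε_in, no salt) — so the divergent grid self-energy
cancels exactly: `E_p = ½ Σ q_i Δφ(r_i)`.  Against the Born closed form
`−(k_e q²/2a)(1/ε_in − 1/ε_out)` (−40.47 kcal/mol at q=1e, a=2 Å, 2/80)
the solver lands within ~1% at 2 grid/Å, improving on refinement; the
acceptance suite asserts the looser 10%/monotone-improvement contract that
finite differencing guarantees in general.

Surface potentials are read at each atom's accessible Shrake–Rupley points
(probe-expanded sphere), averaged per atom, and classified at ±1 kT/e into
negative/neutral/positive; buried atoms are omitted.

## MM/PBSA

Per-entity energy `E = E_c + E_v + E_p + E_np` (the total is the exact
sum by construction).  `E_c` is pairwise Coulomb — inside binding
differences it uses the solute dielectric (ε = 2) by default,
config-exposed since the literature varies.  `E_v` is CHARMM-form LJ with
Lorentz–Berthelot combination.  `E_np = α·SASA + β` with α = 0.0054
kcal/mol/Å², β = 0.92 kcal/mol; SASA is Shrake–Rupley with a deterministic
golden-spiral lattice (default 1000 points, 1.4 Å probe).

Binding uses the single-trajectory scheme: parts are cut from complex
frames unchanged, so intra-part Coulomb and LJ terms cancel exactly and
ΔE reduces to the inter-part MM terms plus solvation differences.  Two
consequences worth flagging:

- ΔE_np carries a constant −β offset (the intercept counts once per
  entity: complex, A, B) on top of α·ΔSASA — a neutral, far-apart,
  LJ-free pair therefore reports ΔE = −0.92 kcal/mol exactly.  This
  follows from composing the four-term entity energy literally; some
  MM/PBSA conventions drop β in differences, which would shift every ΔE
  by +0.92;
- no entropy term is computed.

ΔE is symmetric under swapping the part labels, and the per-frame means
carry the sample SD over the analysis window.

## Synthetic systems and what the tests show

The generators produce the smallest systems for which each downstream
statistic has an exact or closed-form oracle: rigid 4-bead pseudo-domains
whose mass-center distance is drawn Normal(mean, sd) truncated positive by
resampling (unbiased for sd ≪ mean; the default study condition is
mean 10 Å, sd 0.5 Å, 1000 frames at 0.1 ns — a desk-scale stand-in for a
100 ns production run); donor–H–acceptor triples and salt-bridge pairs at
exact geometry probing both sides of every cutoff; ±1e dimers for force
and MM/PBSA sign structure; Born spheres for the PB solver; boolean-mask
occupancy patterns counted integer-exactly.

These systems validate the *machinery* — counting, windowing, projection,
discretization, unit conversions — not force-field realism: they have no
internal flexibility, no conformational coupling between contacts and
cleft size, and idealized charges.  Passing tests therefore certify that,
given real trajectories and parameters, the statistics are computed as
defined; they do not reproduce any particular biological system's values.

## Numerical choices and limitations

- All randomness flows through numpy Generators with explicit seeds; same
  spec + seed is byte-identical, and the CLI writes a config-hash + seed
  run log next to every TSV.
- PDB coordinates round to 3 decimals (5e−4 Å round-trip error); PQR
  charges/radii to 4 decimals.
- Degenerate inputs fail loudly: empty selections, zero total mass,
  coincident mass centers (undefined separation/decomposition axis),
  single-frame confidence intervals, non-positive geometry parameters.
- v1 limits: no mmCIF/DCD/XTC, no altlocs/insertion codes, no nonlinear
  PB or multigrid, no π-stacking/water-mediated contacts, no entropy term,
  no automated lobe-boundary detection (selections come from config).
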