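# Methods

This note records the modelling assumptions, conventions and numerical
choices behind the package, and what its synthetic fixtures do and do not
demonstrate.

## Force-field model

**Functional form.** Harmonic bonds ½k_b(r−r_eq)², GROMOS-96 cosine
angles ½k_θ(cos θ − cos θ_eq)², Lennard-Jones 12-6 with potential shift
to zero at the cut-off, and point-charge Coulomb. No dihedral term
exists: several backbone 3-body angles sit near 180°, where a torsion
defined on top of them is ill-conditioned; the cosine angle form is
smooth there, which is what makes the omission numerically safe at CG
time steps.

**Units and constants.** GROMACS conventions: nm, kJ/mol, g/mol,
elementary charges; angle table entries in degrees, converted to radians
internally. Atomic weights C = 12.0107, H = 1.00794, O = 15.9994 — these
reproduce every tabulated bead mass digit-for-digit when summed over the
bead composition and rounded to three decimals, so bead masses are
*derived* at load time and validated, never stored redundantly. Coulomb
factor f = 138.935458 kJ mol⁻¹ nm e⁻²; R = 8.314462618 J mol⁻¹ K⁻¹;
default cut-off 1.1 nm for both LJ and Coulomb.

**Beads and charges.** Nine bead types. The three glycerol-ester beads
(1CH2OCO, 2CHOCO, 3CH2OCO — one per *sn* position; "CHOCO" is accepted
as an alias of 2CHOCO) carry −0.05 e; the ester-adjacent aliphatic
variants C2H4E and C3H6E carry +0.05 e; all other beads are neutral, so
every TAG is net-neutral by construction. Eighteen free non-bonded
scalars (σ, ε per bead) combine by Lorentz–Berthelot rules.

**Exclusions.** Non-bonded interactions are excluded for first bonded
neighbours only (`nrexcl 1` in emitted topologies); angle partners (1–3
pairs) interact. Exclusions never cross molecules.

## Chain decomposition

A fatty-acid chain is specified by carbon count and double-bond list in
acid (Δ) numbering, C1 = carbonyl carbon. C1 is absorbed into the
glycerol-ester bead. The remaining carbons are decomposed by exhaustive
depth-first search over bead sequences whose every consecutive pair has
a bond-table row, with a CHCH bead forced onto exactly the two carbons
of each double bond (the bond table then forces its C3H6 flanks) and the
terminal three carbons forced into C3H7T. Among complete solutions the
selection key is: fewest two-carbon beads, then C2H4E preferred over
C3H6E for the attachment bead, then C2H4 beads placed nearest the
glycerol end. This rule reproduces the published arachidic mapping
(C2H4E–C2H4–C3H6–C3H6–C3H6–C3H6–C3H7T) and the unique oleic solution,
and is deterministic. Chains the bond/angle tables cannot express (e.g.
7-carbon chains, or a Δ11 double bond whose flank would need a
C3H6–C3H6–CHCH angle with no parameter row) fail loudly — at mapping
time for bond-table violations, at topology-build time for angle-table
violations. *cis*/*trans* geometry is retained as metadata only; the
parameter tables carry a single CHCH bead.

Angles are enumerated exhaustively as all bonded triples of the topology
tree rather than from a whitelist, so an unsupported chemistry surfaces
as an explicit "unparameterized interaction" error naming the triple.

## Energy evaluation

**Scope.** The evaluator exists for fixture energetics, consistency
testing and relaxation — production dynamics belong to the MD engine via
the emitted files. Its Coulomb term is therefore *plain truncated* at
the cut-off (optionally shifted to zero there), not Ewald/PME: charges
are small (±0.05 e) and locally neutral, so truncation errors are tiny
at fixture scale, and implementing mesh Ewald here would duplicate the
engine. This is the one deliberate departure from the production
electrostatics the emitted input files request.

**Periodicity.** Boxes are lower-triangular triclinic (rows = box
vectors). Minimum-image reduction proceeds c→b→a by rounding fractional
components, valid for engine-compliant boxes; every evaluation enforces
that each box extent exceeds twice the cut-off. Pair search is a
vectorised all-pairs distance evaluation in row blocks with cut-off
masking — adequate to the few-thousand-bead systems the fixtures
produce, and verified against an independently written double loop with
explicit 3×3×3 image search.

**Forces.** Analytic throughout. The angle gradient is taken with
respect to cos θ (no 1/sin θ factor), so it is regular at θ → 180°.
Bonded beads at zero separation raise an error rather than being
clamped. Minimization is steepest descent with an adaptive step
(growth 1.2× on accepted steps, halving on rejections, floor 1e-8 nm),
stopping at max |F| below a tolerance (default 10 kJ mol⁻¹ nm⁻¹).

## File formats

`.gro` records are fixed-width with positions on the 3-decimal grid and
velocities on the 4-decimal grid; write∘read is bit-identical and
read∘write is identity up to that grid. Malformed input errors carry
1-based line numbers. The force-field `.itp` uses nbfunc 1 with
combination rule 2 (σ/ε Lorentz–Berthelot), bond function 1, angle
function 2 (G96 cosine); molecule `.itp`s always emit `nrexcl 1`.
Parameter numbers are formatted with `%.6g` (and bond lengths at their
table precision), so every table scalar survives a write/parse round
trip exactly. One residue per TAG molecule; residue name = molecule name
truncated to five characters; atom names = bead type names.

## Analysis estimators

- **Density**: total molar mass / (N_A · V), nm³ → cm³; the series
  variant averages frames in a trailing window. "Last X ns" windows are
  inclusive: t ≥ t_end − X.
- **Lattice parameters**: box rows divided componentwise by the stacking
  counts (default (5,1,5), matching a crystal built by replicating the
  unit cell five times along a and c); lengths plus α(b,c), β(a,c),
  γ(a,b) in degrees. Angles are stacking-invariant, so cell and box
  angles coincide; `box_from_lattice` inverts the construction to
  round-off.
- **RDF**: minimum-image pair histogram, shell-volume and ideal-density
  normalization, frame-averaged; self-pairs excluded for overlapping
  groups; r_max capped at half the smallest box extent.
- **Bonded distributions**: pooled over all instances of one bond-pair
  or angle-triple type across molecules and frames; reports the
  histogram plus mean and standard deviation, the two statistics the
  bottom-up fitting workflow matches.
- **Enthalpies**: ΔH_fus is the difference of windowed means of melt and
  crystal enthalpy series with a percentile-bootstrap CI of resampled
  differences (the CI method is a package choice; repeated runs are
  aggregated by averaging); ΔH_vap = U_gas − U_liq + RT.

## Optimization workflow

The cost of one evaluation is Σ_i wt_i (10 (r_i − r_ref,i)/r_ref,i)²:
zero exactly at the references, quadratic in relative deviation, scale
invariant under joint rescaling of a metric and its reference. The
factor of ten multiplies the *deviation*; the alternative reading (ten
times the normalized metric) is not zero at the reference and is not
used. Costs are minimized here; a maximizing convention with negated
costs and a "highly negative" crash value is equivalent. Crashed or
raising backends are recorded with a large positive penalty (default
10⁶) and kept in the history; the loop never aborts.

The surrogate is a Gaussian process on the unit-cube-scaled parameters
with kernel (quadratic dot-product) + Matérn(5/2) + white noise: the
quadratic component reflects that the cost is a weighted quadratic in
the metrics and hence bowl-shaped near the optimum, the Matérn component
absorbs non-quadratic structure. Penalty costs are capped at one decade
above the worst completed cost before fitting so crashes repel the
surrogate without flattening it. Acquisition alternates
posterior-mean minimization (multi-start L-BFGS-B; three of every four
iterations — the backends here are deterministic, so exploitation
dominates) with expected improvement over global-plus-local candidate
sets. Proposals always respect the bounds; identical seeds and backend
give identical histories. With the reference budgets (30 random training
points, 40 guided iterations) the harness recovers a known 18-parameter
optimum of a quadratic mock backend to within a few percent per
coordinate.

Per-bead bounds and metric weights are configuration inputs
(`bounds_around` builds fractional boxes around the current values as a
convenience); the final parameter set is the componentwise mean of
completed records below a cost threshold.

## Synthetic fixtures

`build_extended_molecule` places every bond and angle exactly at
equilibrium (planar zig-zag chains; branch directions solved from the
cone intersection of the two placed angle constraints; a small discrete
search over chain plane/side choices keeps the chains sterically
separated), so its bonded energy is numerically zero. Lamellar fixtures
replicate this aligned molecule on a rectangular lattice with a 0.45 nm
default gap — close enough that neighbouring chains sit in the
attractive LJ well — and melt fixtures insert randomly rotated copies
with a 0.35 nm hard clearance (≈ the smallest σ) under seeded rejection
sampling.

These fixtures are idealized, not crystallographically faithful: they
contain no β/β′ polymorph packing, no thermal disorder, and no
experimentally constrained cell geometry (which would require external
XRD structures). Tests passing on them demonstrate parameter and
energy-evaluation correctness, file fidelity and workflow recovery — not
that the force field reproduces real polymorph properties, which is the
business of full MD runs driven by the emitted files.

## Problem sizes

The default test and acceptance runs use fixture-scale systems chosen as
the smallest that exercise each property: 420-bead lamellar stacks and
8-molecule melts for the pair-sum oracle, 50 perturbed single-molecule
configurations for force/finite-difference checks, 400-bead × 12-frame
ideal gases for RDF statistics, 500 replicates × 300 resamples for
bootstrap coverage, and the 30 + 40 evaluation budget for optimizer
recovery.

## Known limitations

- Truncated Coulomb in the evaluator (above); emitted files request PME.
- The topology builder covers tri-esterified glycerol only — no mono-/
  di-acylglycerides or phospholipids, and only chemistries the bond and
  angle tables parameterize (e.g. no Δ11 monounsaturates).
- No MD integrator, thermostat or barostat; no melting-point or
  free-energy methods.
- The lamellar generator is a testing surrogate, not a crystal-structure
  predictor.
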