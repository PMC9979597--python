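# cogito-ff

A toolkit for the COGITO coarse-grained force field for triacylglycerides
(TAGs) — the fat molecules of confectionery, oils and biological lipids.
Pure-TAG systems (crystals and melts, no water) are awkward for the common
coarse-grained force fields: aqueous-parameterized bead sets do not
transfer, and three-carbon-only mappings cannot distinguish a palmitic
from a stearic chain. COGITO solves this with **nine interchangeable bead
types** — three glycerol-ester beads (one per *sn* position), an alkene
CHCH bead, two- and three-carbon aliphatic beads (with ester-adjacent
variants carrying +0.05 e against the ester beads' −0.05 e), and a
terminal bead — from which the topology of *any* saturated or unsaturated
TAG can be assembled.

This package is aimed at simulators who want to build, inspect, validate
or re-parameterize such models: it owns everything around the MD engine
(the engine itself, e.g. GROMACS, is driven by the files this package
writes).

## The model

The potential is

```
U = Σ_bonds ½ k_ij^b (r_ij − r_ij^eq)²
  + Σ_angles ½ k_ijk^θ (cos θ_ijk − cos θ_ijk^eq)²
  + Σ_pairs 4 ε_ij [ (σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶ ]  (potential-shifted, r_c = 1.1 nm)
  + Σ_pairs f q_i q_j / r_ij
```

with Lorentz–Berthelot mixing (σ arithmetic, ε geometric), non-bonded
exclusion of first bonded neighbours only, no dihedral term (the cosine
angle form is smooth through 180°, which is what makes that omission
stable), and GROMACS units throughout (nm, kJ/mol, e). The bead masses
derive from atomic composition; the 16-row bond table, 27-row angle table
and 9×2 Lennard-Jones table ship as packaged data.

What the package does:

- **`ff_model`** — the parameter tables, lookups, mixing rules, model validation;
- **`chain_mapper`** — decompose any fatty-acid chain (carbon count +
  double-bond positions) into a legal bead sequence and assemble full TAG
  topologies (bonds, angles, exclusions, charges);
- **`energy_eval`** — potential energy, analytic forces and steepest-descent
  minimization on periodic (triclinic) configurations;
- **`gmx_files`** — `.gro` / `.itp` / `.top` readers and writers with
  digit-exact parameter transcription;
- **`traj_analysis`** — density, unit-cell lattice parameters, RDFs,
  bond/angle distributions, bootstrap enthalpy estimators
  (ΔH_fus from melt/crystal series, ΔH_vap ≈ U_gas − U_liq + RT);
- **`param_opt`** — the top-down Bayesian-optimization workflow: random
  training phase, Gaussian-process surrogate, crash penalties, and
  filter-and-average parameter extraction with the cost
  `Σ_i wt_i (10 (r_i − r_ref,i)/r_ref,i)²`;
- **`fixtures`** — idealized lamellar "crystal" stacks and random melts for
  testing without external crystal structures;
- **`cli`** — `cogito map / build-top / export / energy / minimize /
  analyze / optimize / fixtures`.

## Worked example

Map oleic acid (18 carbons, *cis* double bond at Δ9) and build
1-palmitoyl-2-oleoyl-3-stearoyl-*sn*-glycerol (sn-POSt):

```sh
$ cogito map --chain 18:1c9
C2H4E-C2H4-C3H6-CHCH-C3H6-C2H4-C3H7T
```

```python
from cogito import canonical_model, build_tag, FattyAcidSpec, total_energy, density
from cogito.fixtures import FixtureSpec, build_lamellar

ff = canonical_model()
post = build_tag("POSt", FattyAcidSpec(16),
                 FattyAcidSpec(18, ((9, "cis"),)), FattyAcidSpec(18), ff)
print(post.n_beads, len(post.bonds), len(post.angles))   # 21 20 20
print(post.molar_mass)                                   # 861.413

crystal = build_lamellar(FixtureSpec(post, 20, "lamellar", lattice=(5, 1, 4)), ff)
eb = total_energy(crystal, ff)
print(f"{eb.bond:.4f} {eb.angle:.4f} {eb.lj:.4f} {eb.coulomb:.4f}")
# 0.0000 0.0000 -540.8656 -28.6835
print(f"{density(crystal):.5f}")                         # 0.08270
```

The 21 beads are the three glycerol-ester beads plus 5 + 7 + 6 chain
beads; the molar mass equals the C55H104O6 formula mass to < 0.01 g/mol.
The extended-geometry fixture has zero bond and angle energy by
construction, cohesive (negative) Lennard-Jones and Coulomb energy, and a
low density because the idealized stack is not a close-packed β
polymorph. `cogito export --config run.yaml --out sysdir` writes the
matching `.gro`, `.itp` and `.top` for an MD engine.

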