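# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. It states no result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Elastic network and normal modes

The protein is reduced to one bead per observed Cα. Beads within a cutoff
R_c of each other in the reference structure are connected by springs with
a single uniform force constant; the potential is
V = Σ_contacts (γ/2)(d_ij − d⁰_ij)². The γ/2 convention means γ is the
per-contact curvature: writing the same potential without the ½ (as is
sometimes done, with constant C) simply corresponds to γ = 2C. The default
γ = 1 makes every eigenvalue, fluctuation and stiffness a *relative*
quantity; nothing in the package calibrates γ to kcal/mol, so only
comparisons computed under one parameterization (wild-type vs mutant, lobe
vs lobe) are meaningful. Absolute Å² fluctuation values would require an
experimental calibration of γ that the package deliberately does not
attempt.

Defaults: R_c = 15 Å (mid-range of the physically sensible 8–20 Å window
for Cα networks and a common anisotropic-network default), no mass
weighting (uniform beads), dense symmetric eigendecomposition
(`scipy.linalg.eigh`; the intended regime is N ≲ 1000, where a 3N×3N dense
solve is seconds).

**Zero-mode handling.** Eigenvalues at or below 1e−8·λ_max are counted as
rigid-body modes and discarded. Two guards protect this split: a connected
3-D network must yield exactly six zero modes (any other count raises a
structural warning — it almost always means a disconnected contact graph,
which `build_hessian` also detects and reports with its component count),
and the largest discarded eigenvalue must sit at least three orders of
magnitude below the smallest retained one, otherwise the computation
refuses to proceed rather than silently misclassifying a soft internal
mode. Mode indices in every API and report are 1-based over *non-zero*
modes, the way modes are quoted in the literature.

**Degenerate geometries.** A distance-only spring network has spurious
zero-energy mechanisms when a bead's contacts are collinear or coplanar
(torsion about a straight linker, transverse motion of a bead whose
neighbors all lie in one plane). The synthetic dumbbell deliberately avoids
these by giving its linker a helical offset; the guards above surface them
on real input.

## Observables

* Square fluctuations use the softest m modes (default 100, or all if
  fewer); the full-spectrum value equals the block trace of the Hessian
  pseudo-inverse, which is the oracle used in the tests.
* The effective pair force constant κ_ij inverts the mode-summed compliance
  of the inter-site distance projected on the reference unit vector. For a
  lone spring this evaluates to the spring constant γ itself (the single
  mode contributes compliance 2/λ = 1/γ), which the analytic dimer test
  asserts. Stiffness requires the complete non-zero spectrum; a partial
  mode set is refused rather than silently approximated. The per-residue
  stiffness is the mean of κ_ij over all partners j.
* Collectivity is the exponential-entropy measure on normalized squared
  site amplitudes, in [1/N, 1]; zero-amplitude sites contribute zero.

## Pulling-axis alignment and mode selection

The experiment fixes one direction: the vector between the two
tether-attachment residues (modeled at their Cα beads). The structure is
rotated so this vector lies exactly along the chosen axis (z by default);
the spin about that axis is physically unconstrained and left free by using
the minimal rotation, and the centroid is moved to the origin for numerical
hygiene. Eigenvalues are rotation-invariant, so alignment changes only how
the eigenvectors decompose onto the axis.

Published practice selects domain-separating modes by visual inspection of
the low modes and the most collective modes. The package codifies this:
candidates are the union of the first 10 non-zero modes and the 10 most
collective of the first 50; a candidate is selected when its two domain
mean axis-components have opposite signs and their gap is at least 25 % of
the best candidate gap. The min-separation default is a reproducibility
device, not physics — the full per-candidate report (eigenvalue,
collectivity, domain means, separation) is always emitted so a human can
override the rule, which preserves the judgment-based intent of the
procedure. Domain means are computed on the raw orthonormal eigenvectors,
not 1/√λ-scaled ones; scaling would re-weight the ranking toward soft modes
that the candidate pool already favors.

## Deformation

Deformed conformations are linear displacements along eigenvector
combinations, rescaled so the raw RMSD to the reference is exact (a unit
3N eigenvector at amplitude s gives RMSD s/√N, hence the closed form
s = target·√N for a single mode). Stochastic ensembles draw one standard
normal coefficient per selected mode, scaled by 1/√λ_k by default so softer
modes dominate as they would thermally; an `equal` weighting is provided
because the stochastic scheme used by existing ensemble generators is not
fully documented, and reports record which was used. The rescale removes
the overall amplitude scale either way, so the weighting only shapes the
*direction* distribution.

Randomness goes through one seeded `numpy` generator. RMSD-ramp steps and
pipeline ensembles derive sub-seeds by a stated splitting rule
(`SeedSequence(entropy=seed, spawn_key=(index,))`, reduced below 2³¹), so
any step can be reproduced in isolation; all post-rescale coefficients are
logged and reproduce every frame exactly.

A deliberate limitation: frames are Cα traces displaced linearly, with no
re-minimization or side-chain rebuilding. At 12 Å RMSD they are locally
unphysical and are interpreted *only* through ensemble statistics of the
buried volume, never as structures. A sanity cap (default 20 Å) rejects
amplitude requests far outside the regime where this reading makes sense.
A corner case worth knowing: a single-mode ensemble collapses, after the
exact-RMSD rescale, to a two-point distribution (± the deterministic
deformation) — only the sign of the draw survives.

## Buried volume

Deformed frames carry only Cα positions, so burial uses a single unified
residue-sphere model for both intact and deformed structures: each residue
is a sphere centered on its Cα with the radius that reproduces its
literature mean residue volume (bundled table, Zamyatnin 1972; unknown
residue names fall back to the glycine volume with a warning). Exposure is
the fraction of golden-spiral quadrature points on the probe-inflated
sphere (probe 1.4 Å, 960 points) not occluded by any neighbor's inflated
sphere — a deterministic, seed-free Shrake–Rupley analogue that is
bit-exact at fixed point count. A residue is buried when its exposure falls
below 0.05 (no published criterion exists to copy; the threshold is
configurable and always reported next to the volumes it produced). A
domain's buried volume is the summed table volume of its buried members;
ensemble statistics report mean ± sd overall and restricted to frames with
non-zero buried volume, since fully-unfolded frames otherwise dilute the
mean.

The residue-sphere model is coarser than all-atom solvent accessibility on
intact structures (an all-atom cross-check on crystal structures is the
natural extension); its virtue is that intact-vs-deformed comparisons use
one consistent geometry. Quadrature convergence (doubling the point count
changes no fraction by more than 0.01 on the fixtures) and rigid-motion
invariance to sampling tolerance are asserted in the tests.

## Synthetic fixtures

Three generated models give every stage an analytic or constructed ground
truth without any structure download:

* **dimer** — two beads, one spring: eigenvalue 2γ, five zero modes,
  pair force constant γ, all known in closed form;
* **helix** — ideal α-helix trace (rise 1.5 Å, 100°/residue, radius
  2.3 Å, consecutive Cα distance ≈ 3.8 Å): a connected one-body network
  with the classic floppy-end fluctuation profile;
* **dumbbell** — two quasi-spherical lobes (rejection-sampled uniform
  sphere packings, minimum bead distance 3.4 Å) joined by a helically
  offset linker, with domain map and tether attachments at the outermost
  beads. Defaults: 36 beads per lobe at packing radius 7.8 Å, linker of 6
  beads, lobe-center separation 40 Å — chosen so each lobe holds a genuine
  multi-residue buried core under the default burial parameters, the
  linker is a soft joint (clearly lower stiffness than the lobes), and the
  two lobes interact only through the linker, giving a clean
  lobe-separation mode. An asymmetric dumbbell (one lobe packed 30 %
  looser) is the parameter-recovery target: the looser lobe has lower
  buried volume already in the undeformed structure and must be ranked
  lower-integrity by the full pipeline.

What the fixtures do *not* emulate: real secondary-structure topology,
sequence-dependent packing, or anisotropic domain shapes. Passing the
fixture-based tests therefore demonstrates correctness of the mechanics
(Hessian, modes, selection, deformation, burial bookkeeping) and
end-to-end recovery of a constructed packing asymmetry — not predictive
accuracy on real proteins, which is exercised separately by the case-study
checks that require the corresponding RCSB entries on disk.

## Pipeline

A run executes the five stages (survey → align → modes → observables and
selection → ensembles and burial) for the base structure and each named
truncation, from one validated YAML/JSON config (unknown keys are
rejected). Truncation chaining is an ordered list of named residue-range
removals; deciding *what* to truncate next is judgment-based and is not
automated. Every plotted series exists as CSV; plots are never
load-bearing. The manifest echoes the config, versions, per-stage timings
and all warnings (disconnected networks, skipped residues, fallback
volumes), and identical config + seed reproduces byte-identical tables.

Problem sizes in the shipped tests and the acceptance script are chosen to
keep a full run on one CPU in well under a minute per configuration:
10–40-bead fixtures for the analytic oracles, 78-bead dumbbells with
ensembles of 50–100 frames for the end-to-end checks, and 20 replicates
for the recovery-rate experiment. All sizes scale up by config.
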