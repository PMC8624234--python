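# pullnma

Elastic-network normal-mode analysis for interpreting single-molecule force
spectroscopy experiments on proteins.

Optical-trap pulling experiments report one-dimensional force spectra:
unfolding "rips" whose structural identity — *which* domain came apart, and
in what order — has to be inferred by other means. Steered molecular
dynamics can do this but is expensive. `pullnma` implements the cheap
alternative: harmonic analysis of a Cα elastic network, oriented along the
experimental pulling axis, combined with buried-core volume as a proxy for
domain structural integrity.

## The model

Each residue is a bead at its Cα position. Beads closer than a cutoff
*R<sub>c</sub>* (default 15 Å, sensible range 8–20 Å) in the reference
structure are joined by identical harmonic springs:

V = Σ_{d⁰ᵢⱼ < R_c} (γ/2) (dᵢⱼ − d⁰ᵢⱼ)²

Diagonalizing the 3N×3N Hessian of this potential gives eigenpairs
(λₖ, **a**ₖ): six zero modes for rigid-body motion of a connected network,
and 3N−6 internal modes whose softest members describe domain-scale motion.
From these the package computes the standard observables:

* **square fluctuations** fᵢ = Σₖ λₖ⁻¹ |**a**ₖ,ᵢ|² over the softest modes,
* **mechanical stiffness** (effective pair force constant, full spectrum):
  κᵢⱼ = [Σₖ λₖ⁻¹ ((**a**ₖ,ⱼ − **a**ₖ,ᵢ)·ê₀ᵢⱼ)²]⁻¹, averaged over partners,
* **collectivity** κₖ = exp(−Σᵢ pᵢ ln pᵢ)/N with pᵢ ∝ |**a**ₖ,ᵢ|²,
* **separating modes**: after rotating the molecule so the tether vector
  lies along z, the modes whose per-domain mean z-components have opposite
  signs — the motions an applied force is expected to amplify,
* **target-RMSD ensembles**: stochastic mode combinations rescaled so each
  frame sits at an exact RMSD from the reference, evaluated statistically,
* **buried-core volume**: residues whose solvent exposure (residue-sphere
  model, golden-spiral quadrature) falls below a threshold, summed as
  literature mean residue volumes per domain. The domain whose ensembles
  retain the least buried volume is predicted to lose structural integrity
  first.

All fluctuation/stiffness outputs are in γ-normalized (relative) units;
the spring constant is never calibrated to absolute energies.

## Worked example

The synthetic dumbbell is a two-lobe bead model with a built-in ground
truth: lobe B is packed 30 % looser than lobe A, so it should be flagged as
the structurally weaker domain. Configure a run:

```yaml
# dumbbell.yaml
structure:
  fixture:
    kind: dumbbell
    n_per_lobe: 36
    lobe_packing_radius: [7.8, 10.14]   # lobe B packed 30% looser
    separation: 40.0
    seed: 2
enm: {cutoff: 15.0, n_modes: all}
deformation:
  target_rmsd: 12.0
  ramp: [4.0, 8.0, 12.0]
  n_conformations: 100
  n_per_step: 25
output_dir: dumbbell_out
seed: 1
```

```text
$ pullnma run --config dumbbell.yaml
run complete; manifest at dumbbell_out/manifest.json
full: lowest-integrity domain = lobeB
```

The integrity ranking (`dumbbell_out/full/integrity_ranking.csv`) holds the
buried-volume statistics of the 12 Å ensemble behind that one-line verdict:

```text
domain  mean_buried_volume  sd_buried_volume  n_nonzero_frames  integrity_rank
 lobeB              90.372        137.362474                46               1
 lobeA             385.410        215.696289               100               2
```

Lobe B retains a mean of 90 Å³ of buried core over the 100 distorted
conformations (and has already lost its core entirely in 54 of them), while
lobe A keeps 385 Å³ and never fully unfolds — the pipeline recovers the
packing asymmetry that was built into the fixture. The same directory
contains the per-residue fluctuation/stiffness table, the per-mode
selection report with collectivities and domain mean z-components, the
ensembles as multi-model PDB, and plots of each CSV series.

The individual stages are also available as subcommands (`modes`, `fluct`,
`stiffness`, `select`, `deform`, `burial`, `fixtures`) and as a Python API
(`pullnma.compute_enm_modes`, `pullnma.select_separating_modes`,
`pullnma.sample_ensemble`, `pullnma.ensemble_burial`, ...).

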