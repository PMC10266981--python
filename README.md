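# brainmodes

Geometric eigenmodes of brain structure, and wave-based models of brain
activity built on them.

A long line of work in neural field theory holds that large-scale brain
activity is shaped less by the detailed wiring between regions than by the
geometry of the tissue the activity propagates through. `brainmodes` is a
tested, reusable implementation of that analysis for computational
neuroscientists: it derives the resonant spatial basis of a structure — the
eigenfunctions ψ_j of the Laplace–Beltrami operator, Δψ_j = −λ_j ψ_j —
directly from a surface or volume mesh, and provides everything needed to
put geometry-based and connectome-based accounts of brain activity on the
same footing:

- **Mode derivation.** Linear-FEM Laplace–Beltrami eigenmodes of triangle
  meshes (cortical sheets) and tetrahedral meshes (solid structures such as
  thalamus-like volumes); graph-Laplacian eigenmodes of vertex-level
  connectomes and of synthetic graphs wired by the exponential distance
  rule, P(connect) = e^{−αd}.
- **Modal decomposition.** Expansion of activation maps and time series as
  y = Σ_j a_j ψ_j with mass-matrix quadrature (a = ΨᵀMy); reconstruction
  accuracy vs mode count, parcel FC reconstruction, normalized modal power
  spectra P_j = |a_j|²/Σ|a_k|², sequential mode-removal analyses,
  smoothing-surrogate comparisons and spin-test spatial nulls.
- **Dynamics.** An isotropic damped wave model (damping γ_s, length scale
  r_s) integrated exactly in the mode basis; a balanced
  excitation–inhibition neural-mass model; the Balloon–Windkessel
  haemodynamic stage producing BOLD.
- **Model–data benchmarks.** Edge FC, node FC, and functional connectivity
  dynamics (FCD) with its Kolmogorov–Smirnov statistic, plus grid fitting of
  the wave length scale r_s.
- **Functional gradients.** Connectopic mapping of 3D structures (SVD
  reduction, η² fingerprint similarity, Laplacian Eigenmaps) and
  quantitative matching of gradients to geometric modes.
- **Synthetic data.** Seeded generators for sphere-like cortices, BOLD-like
  time series with planted modal spectra, EDR connectomes, and volumes with
  planted functional gradients — every dataset ships its planted truth.

Eigengroups follow the spherical-harmonic analogy: group l contains the
2l+1 modes with indices l²+1…(l+1)² and has spatial wavelength
2πR_s/√(l(l+1)), with R_s = 67.0 mm for the population-averaged template.

## Worked example

```python
import brainmodes as bm

# an idealized cortical surface: icosphere at the template radius
mesh = bm.make_icosphere(4, 67.0)
basis = bm.solve_modes(bm.assemble_lbo(mesh), 50)

# eigengroup wavelengths on the template sphere
for mode in (10, 50, 100, 200):
    l = bm.mode_to_group(mode)
    wl = bm.eigengroup_wavelength(l, R_s=67.0)
    print(f"mode {mode:3d} -> eigengroup l={l:2d}, wavelength {wl:6.1f} mm")

# decompose a synthetic activation map and reconstruct it
parc = bm.make_parcellation(mesh, 50, seed=0)
y, truth = bm.synth_task_map(basis, {1: 2.0, 4: 1.0, 9: 0.5},
                             noise_sd=0.002, seed=1)
for n_use in (2, 5, 10, 50):
    r = bm.reconstruction_accuracy_map(bm.SpatialMap(y), basis, parc, n_use)
    print(f"reconstruction accuracy with {n_use:2d} modes: r = {r:.3f}")
```

prints

```
mode  10 -> eigengroup l= 3, wavelength  121.5 mm
mode  50 -> eigengroup l= 7, wavelength   56.3 mm
mode 100 -> eigengroup l= 9, wavelength   44.4 mm
mode 200 -> eigengroup l=14, wavelength   29.0 mm
reconstruction accuracy with  2 modes: r = 0.889
reconstruction accuracy with  5 modes: r = 0.979
reconstruction accuracy with 10 modes: r = 1.000
reconstruction accuracy with 50 modes: r = 1.000
```

The wavelengths say which spatial scales each part of the mode basis
captures (the group of mode 10 spans patterns ~120 mm across; by mode 200
the basis resolves ~30 mm). The accuracy column shows the map — planted on
modes 2, 5 and 10 with a little vertex noise — being recovered as soon as
the basis includes the planted modes, the logic behind judging how many
modes brain maps actually need.

A thin CLI covers the common entry points:

```bash
brainmodes mesh validate surface.off
brainmodes modes --surface surface.off --n 200 --out basis.npz
brainmodes simulate-wave --mesh surface.off --parcellation labels.txt \
    --rs 28.9 --frames 1200 --out bold.txt
brainmodes fcmetrics --model bold.txt --data ref.txt --tr 0.72
```

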