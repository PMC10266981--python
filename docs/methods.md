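# Methods

## The model in brief

`brainmodes` treats the geometry of a brain structure as the primary
constraint on its activity. The resonant basis of a surface or volume is the
eigenfunctions of the Laplace–Beltrami operator (LBO),

    Δψ_j = −λ_j ψ_j ,      0 = λ_1 ≤ λ_2 ≤ … ,

and the package derives that basis, expands activity in it, and simulates
wave dynamics whose spatial part is diagonal in it. Three mode families are
supported: **geometric** modes from mesh geometry (triangle or tetrahedral
P1 finite elements), **connectome** modes from the graph Laplacian of a
vertex-level connectivity graph, and **EDR** modes from a graph wired
stochastically with connection probability exp(−αd) in Euclidean distance d.

## Discretization

The LBO is discretized with linear (P1) finite elements: the cotangent
stiffness matrix K and the consistent mass matrix M (element mass
A/12·(1+δ_ij) on triangles, V/20·(1+δ_ij) on tets). Eigenpairs solve the
generalized problem K ψ = λ M ψ by shift-invert Lanczos with shift −10⁻⁸
(so the singular K factors) at machine-precision tolerance. A loose ARPACK
tolerance can silently drop members of degenerate clusters — we verified
this against dense generalized eigensolves on coarse spheres — hence the
tight default. Accuracy is controlled by mesh resolution: on an icosphere at
subdivision 4 the first seven eigenvalue clusters match l(l+1)/R² within 2%
and eigenspaces align with spherical harmonics to <5°. Cubic elements would
converge faster per vertex; linear elements keep the assembly dependency-free
and transparent, with resolution as the accuracy dial.

Signs and within-group order of (near-)degenerate modes are not
identifiable; we fix the largest-magnitude entry of each mode positive and
order equal-eigenvalue clusters by the index of that entry.

Eigengroups follow the spherical analogy: group l holds the 2l+1 modes with
1-based indices l²+1…(l+1)², and carries wavelength 2πR_s/√(l(l+1)) with
R_s = 67.0 mm for the population-averaged template (group 0, the constant
mode, has no finite wavelength).

## Volumes

Solid structures are meshed by a deterministic lattice scheme: each voxel of
a (single 6-connected component) binary mask splits into 5 tetrahedra with
parity-alternating diagonals, so shared faces conform and total volume is
conserved exactly. This replaces marching-cubes + external meshers: it is
reproducible, dependency-free, and adequate for eigenmode computation on
smooth synthetic masks, at the cost of a stair-stepped boundary. Vertex
fields interpolate to voxel centres as the mean of the 8 corner values.

## Modal decomposition

Amplitudes discretize the surface integral a_j = ∫ y ψ_j dr with the FEM
mass matrix: a = ΨᵀM y (exact on the basis span; identity inner product for
graph bases). Masked maps fall back to least squares on unmasked vertices.
Reconstruction accuracy is the Pearson correlation of parcellated empirical
vs reconstructed maps (for time series: correlation of the upper triangles
of the two parcel FC matrices). Modal power is P_j = |a_j|²/Σ|a_k|².

Two consequences of the correlation metric worth knowing: it is invariant to
the constant mode (so removing mode 1 alone never changes accuracy — the
mode-removal comparison is meaningful from the first non-constant removal
onward), and it is insensitive to global scaling.

Smoothing surrogates for power-spectrum comparison are white vertex maps
smoothed by iterated neighbour averaging; the iteration count is calibrated
from the mean squared edge length so the kernel approximates a Gaussian of
the requested FWHM, with a fractional relaxation step for continuity. The
spectra are compared by MSLE = mean[(log(1+P_a) − log(1+P_b))²]; log1p keeps
zero powers finite (conventions for this error vary across the literature).

The spin test builds its null by random 3D rotations of parcel centroids
with nearest-centroid reassignment; P is the one-sided fraction of null
Spearman correlations exceeding the empirical one. Under independence the
null p-value is uniform (checked by KS over 200 replicates).

## Wave model

Neural activity obeys an isotropic damped wave equation without
regeneration, with damping γ_s = 116 s⁻¹ (electrophysiological estimate)
and free length scale r_s (default 28.9 mm, the optimum reported for
resting fMRI). Projected onto eigenmodes it decouples into oscillators

    ä_j + 2γ ȧ_j + γ²(1 + r_s²λ_j) a_j = γ² q_j(t),

which we integrate with the exact per-step matrix exponential for
piecewise-constant input — implemented as a per-mode second-order IIR filter
whose poles are exp((−γ ± iω_j)dt), ω_j = γ r_s √λ_j. Impulse responses
match the closed forms (γ²t e^{−γt} critically damped; (γ²/ω) e^{−γt} sin ωt
underdamped) to machine precision. The step bound dt ≤ 0.1/γ_s only limits
how finely the input is resolved; the propagator itself is exact.

Resting state: unit-variance white noise per vertex per step (FC metrics are
scale-invariant, so the amplitude is inert and merely exposed), projected to
modes, integrated, parcellated, passed through the Balloon stage on a
bin-averaged ≤10 ms grid, and sampled at TR = 0.72 s after a burn-in.
Evoked: a deterministic pulse (default 1 ms at 20 s⁻¹ over a vertex ROI,
100 ms window at 0.1 ms) whose response is linear in the stimulus; regional
time-to-peak indexes propagation order.

## Neural-mass (BEI) model

Coupled excitatory/inhibitory gating equations per region with sigmoidal
rate functions H(x) = x/(1 − e^{−dx}) (continuous through H→1/d at
threshold), interregional coupling G·J·C·S^(E), Euler–Maruyama at 1 ms with
noise σ√dt. Fixed-parameter values are not hard-wired to any published fit; the defaults are standard for this model family (τ_E=0.1 s,
τ_I=0.01 s, γ=0.641, a_E=310, b_E=125, d_E=0.16, a_I=615, b_I=177,
d_I=0.087, I_0=0.382, W_E=1, W_I=0.7, J=0.15) and should be set explicitly
for quantitative work. Tests rely only on structural properties:
deterministic fixed points (cross-checked by root finding), the sigmoid
limit, and invariance of S^(E) in [0,1].

## Haemodynamics

The Balloon–Windkessel stage (κ=0.65 s⁻¹, γ=0.41 s⁻¹, τ=0.98 s, α=0.32,
ρ=0.34, V0=0.02, k1=3.72, k2=k3=0.53; 3T constants) integrates vasodilatory
signal, inflow, volume and deoxyhaemoglobin by Heun's method from rest,
which is an exact fixed point of the equations (zero drive gives identically
zero BOLD). BOLD is the algebraic readout y = V0[k1(1−q)+k2(1−q/v)+k3(1−v)]
by default; `bold_as_ode=True` instead integrates that expression as a
differential equation, a variant that appears in some formulations. The two
differ and the algebraic form is the field's standard.

## FC benchmarks and model fitting

Edge FC: Pearson correlation of Fisher-z upper triangles (clipped at
1−10⁻⁶). Node FC: correlation of mean regional strengths, with the diagonal
included in the strength definition. FCD: band-pass 0.04–0.07 Hz (order-2 Butterworth, zero-phase
filtfilt), Hilbert transform, two-quadrant argument θ = tan⁻¹(H/x)
(a four-quadrant option exists; the two differ when x<0 but only
differences enter through cosines), synchrony Δ(i,j,t) = cos(θ_i−θ_j) over
i>j, and the cosine similarity φ_uv of Δ vectors between frames — the
normalizer d_x uses the same i>j index set, excluding the diagonal. Ten
frames at each end are dropped against filter edge effects. Distributions of
upper-triangle FCD values are compared by the two-sample KS statistic, with
pooling across realizations.

The wave model's single free parameter r_s is fitted on a 20-value grid,
10–100 mm, selecting the FCD-KS minimizer. The scaled-down self-consistency
experiment used in testing runs an icosphere (subdivision 3, radius 67 mm),
50 modes, 48 parcels, 450 frames per realization with two realizations
pooled per grid value; at this scale pooling is what keeps the KS landscape
identifiable around the planted value (the KS noise floor scales like the
inverse square root of the pooled frame count).

## Connectopic mapping

Outside-ROI time series are column-centred and SVD-reduced to T−1
components; fingerprints are Pearson correlations of ROI voxels with the
reduced columns; similarity is η² (profiles compared around their pairwise
elementwise means and joint grand mean, the convention of the connectopic-
mapping literature); the group-mean S feeds
Laplacian Eigenmaps: (D−S)v = λDv with S used directly as affinity (the
most literal reading; no k-NN sparsification), the constant eigenvector
dropped, and variance explained reported as (1−λ_i)/Σ(1−λ_j) over retained
gradients — one defensible convention among several, stated because the
source prints none. Gradients are matched to volumetric modes by maximal
absolute spatial correlation, acknowledging arbitrary signs and within-group
order flips.

## Synthetic data

Generators are pure functions of their seed and ship a PlantedTruth record;
recovery tests read truth only from that record. Defaults emulate the study
conditions: icosphere subdivision 4 (2,562 vertices, template radius
67 mm), 50 regions by farthest-point parcellation, BOLD at TR 0.72 s ×
1,200 frames. Modal amplitudes are AR(1) (coefficient 0.8 — a modelling
convenience so FCD is non-trivial; empirical amplitude dynamics are
unknown) with variance ∝ (1+λ/λ₂)^(−exponent); the normalization by the
first nonzero eigenvalue makes the planted spectrum scale-invariant, since
raw eigenvalues on a 67 mm sphere are O(10⁻²) mm⁻² and would otherwise
leave the profile flat. Gradient volumes drive voxels with latent signals
whose loadings are Gaussian bumps in planted-axis space (40 latents, bump
width 1.5 axis-SD, per-axis scale decay 0.6^k), so fingerprint similarity
decays along the planted axes.

What the generators do *not* emulate: scanner noise physics, motion,
regional haemodynamic variability, cortical folding beyond band-limited
bumps, and tractography biases. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated noise
models — not empirical claims about human data, which require the original
datasets and are explicitly out of scope.

## Numerical choices and limitations

- Coordinates in mm, right-handed; indices 0-based internally, 1-based in
  mode numbering as used throughout the field.
- Thresholding tie-break: descending weight then lexicographic (i,j) —
  determinism where no convention is established.
- Fisher-z clipping at |r| = 1−10⁻⁶; correlation of zero-variance vectors is
  an error, not NaN.
- EDR fits use a free amplitude (w ≈ A e^{−αd}): fitting a pure e^{−αd} to
  max-normalized weights is biased whenever the minimum inter-vertex
  distance is well above zero.
- The eigengroup/wavelength correspondence assumes near-spherical topology;
  on strongly folded meshes group boundaries blur and the mapping is an
  approximation whose degradation we note but do not quantify.
- Closed surfaces only for surface eigenmode work (no boundary-condition
  variants); assembly itself accepts open patches with natural boundary
  conditions.
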