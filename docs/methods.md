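# Methods

## Forward model

The head is a domain Ω ⊂ R² (default) or R³ with L surface electrodes e_ℓ.
The quasi-static conduction model at 1 kHz is the complete electrode model
(CEM): ∇·(σ∇u) = 0 in Ω with, on each electrode,
u + z_ℓ σ ∂u/∂n = U_ℓ and ∫_{e_ℓ} σ ∂u/∂n dS = I_ℓ, zero current density on
the remaining boundary, and the charge/ground conventions ΣI_ℓ = ΣU_ℓ = 0.
Permittivity is recorded in the tissue table but not used: the inversion is
real-valued conductivity only.

Discretisation is standard P1 FEM in the pair (u, U). σ is also P1
(nodal); since ∇φ is element-constant, all stiffness and regularization
integrals are evaluated exactly with one-point quadrature. The zero-mean
voltage constraint is imposed by expanding U in a basis of the zero-sum
subspace of R^L, which removes the constant nullspace; the symmetric system
is factorised once per conductivity (sparse LU) and reused for all current
patterns and for the adjoint solves. The Jacobian of an observed channel
mᵀU^{(k)} with respect to a nodal conductivity coefficient is
−∫ φ_j ∇u^{(k)}·∇w^{(m)} dx with w^{(m)} the CEM solution driven by the
measurement pattern m; with adjacent differential channels this costs L
extra solves per conductivity regardless of the number of injections.

Measurements: L pairwise injections (source ℓ, sink ℓ+s mod L, 1 mA) with
skip s = ⌊L/2⌋ − 4, so that source and sink are nearly opposite and current
is forced through the skull; all L adjacent differential channels are
recorded per injection (a mask can drop channels touching injecting
electrodes). Additive i.i.d. Gaussian noise; the experiment driver fixes
the std at 0.067 % of the maximum healthy-frame amplitude, the noise level
of a prototype stroke-EIT device. Contact impedances default to
z_ℓ = 10⁻³ Ω·m² (uniform, assumed known); the model treats them as fixed.

## Phantoms and the two-mesh protocol

The head phantom is four concentric layers (outer radii 90, 85, 78, 76 mm:
scalp, skull, CSF, brain) with literature conductivities at 1 kHz
(scalp 0.32, skull 0.02, CSF 2.0, white matter 0.06, gray matter 0.10,
blood 0.70 S/m). The hemorrhage is a set of nested spheres/discs
(10–30 mm diameter in 5 mm steps) whose shells switch from brain tissue to
blood as the bleed grows; the cortical location displaces white matter near
the brain surface, the deep (basal-ganglia) location gray matter near the
centre. Mesh nodes are placed on rings (2D) or Fibonacci shells (3D) at
every interface radius, with radii inflated so each discretised interface
encloses exactly the analytic area/volume; elements are labelled by
centroid. Element-to-node conversion of tissue values is volume-weighted
averaging, which smears interfaces over one element layer — both the thin
CSF shell and this smearing are deliberately kept, as they are the dominant
sources of realistic modeling error.

To avoid the inverse crime, data are simulated on a fine mesh
(h ≈ 4 mm, ≈3300 elements) while the inversion uses a coarser potential
mesh (h ≈ 6.5 mm) and a coarser-still conductivity mesh (h ≈ 9 mm,
≈550 unknowns) coupled by P1 interpolation; the simulation mesh has ≥4×
the elements of the inversion meshes and an independent node layout.

The structural reference image κ (the stand-in for the admission CT) is the
piecewise compartment indicator 0/1/2 on scalp/skull/inside-skull, built on
the conductivity mesh. Its per-element gradient defines the edge set
(‖∇κ‖ ≥ 0.5·max, where the indicator γ = γ₁ = 0.01, else γ = 1) and the
unit normals ν̂; the region of interest is the brain compartment
(including the hemorrhage shells, excluding CSF). Only the level-set
geometry of κ matters, so the values 0/1/2 are arbitrary.

## Inversion algorithms

All three minimise a generalized Tikhonov objective
‖L_e(V − U(σ))‖² + p(σ).

**Whitening and the modeling-error floor.** At desk-scale discretisations
the two-mesh FEM error is 30–100× the device noise. Whitening by the
device noise alone then makes the Gauss–Newton normal equations absurdly
data-dominated: directions crash the iterate into the positivity bound and
the regularization becomes irrelevant. The solvers therefore whiten with an
effective error level max(noise std, RMS residual of the initial fit) — a
cheap one-number proxy for the approximation-error covariance (config flag
`GNSettings.error_floor`; switching it off restores pure noise whitening).
With this scaling the regularization weights below are balanced and stable
across phantom sizes.

**TV absolute imaging.** Each frame is inverted independently with smoothed
TV, p = α∫(‖∇σ‖² + β²)^½ dx (α = 0.01, β = 0.001), from the best-fitting
constant conductivity; δσ by subtraction. Lagged Gauss–Newton: the TV
weights 1/√(‖∇σ‖²+β²) are frozen when forming the (sparse, PSD) Hessian;
each step solves the dense normal equations and backtracks with projection
to σ ≥ σ_min. The line search warm-starts from the previously accepted step
and freezes direction components that press against an active bound (a
projected direction is otherwise not guaranteed to descend). Stopping:
relative cost decrease < 10⁻⁴ or 25 iterations.

**Linear difference imaging.** Linearisation point σ₀ fitted to the first
frame; closed-form Tikhonov solve of
(JᵀΓ_δe⁻¹J + Γ_p⁻¹)δσ = JᵀΓ_δe⁻¹δV with Γ_δe = Γ_e1 + Γ_e2 and the
squared-exponential smoothness prior with std(σ) = 2σ₀ and correlation
length solved from a 1 % correlation at distance l_Ω/4 (l_Ω = front-to-back
extent of the head). No positivity on δσ — its sign is informative. Dense
Cholesky; fine below a few thousand unknowns.

**Monitoring algorithm (nonlinear ROI difference imaging).** State
σ̃ = (σ₁, δσ) with σ₂ = σ₁ + Kδσ and K the sparse zero-extension from ROI
nodes to Ω, so supp(δσ) ⊆ Ω_ROI by construction. Stacked residual over both
frames; priors p = WTV(σ₁) + TV(δσ) with the parallel-level-sets tensor
B(κ) = I − (1−γ)ν̂ν̂ᵀ making conductivity edges aligned with the reference
image cheap (factor γ₁ along ν̂). Defaults α_δσ = 0.005, α_σ1 = 0.01,
β = 0.001 (α_σ1 is geometry/scale dependent and config-exposed).
Initialisation: δσ = 0 and σ₁ from an anatomically guided three-compartment
fit (one value per scalp/skull/brain, nonlinear least squares on the log
scale, bounded to [0.01, 3] S/m — without bounds a thin-layer
series-resistance degeneracy drives one compartment to zero). Outer lagged
Gauss–Newton with the same projected/warm-started line search, positivity
σ₁ > 0 and σ₁ + Kδσ > 0.

The search direction solves (J̃ᵀL̃ᵀL̃J̃ + H_prior)d = rhs matrix-free by
prior-conditioned LSQR: with FᵀF = H_prior (dense Cholesky of the jittered
block prior Hessian, jitter ε = 10⁻⁸ on the mass-matrix trace scale), the
substitution d = F⁻¹w turns the system into a damped least-squares problem
solved by LSQR using only products with J̃, J̃ᵀ, F⁻¹, F⁻ᵀ (300 iterations,
tol 10⁻⁸ by default; hitting the limit returns the current iterate with a
flag). On small well-conditioned instances the direction matches a dense
normal-equations solve to solver precision (oracle-tested).

Because frame-invariant modeling errors are absorbed by the σ₁ block, the
δσ estimate is comparatively shielded; this is verified as a property test
(a 2 % global conductivity bias applied to both frames moves σ̂₁ more than
δ̂σ).

## Detectability score

For every ordered state pair (D₁, D₂), D₂ ≥ D₁, each algorithm produces
δ̂σ and its integral I = ∫δσ dx (exact vertex-quadrature sum). Per
algorithm and location, integrals are normalized by max|I| over all pairs,
and Q = Ĩ − max_k|Ĩ(D_k,D_k)| subtracts the largest no-growth magnitude as
a noise-floor proxy; diagonal Q is ≤ 0 by construction and Q > 0 marks
detections. Frames are simulated once per state and location (independent
noise for the first-frame and second-frame role, so no-growth pairs differ
by noise only) with per-state seeds derived deterministically from the
master seed. "Volumes" of the 2D disc states are reported on the
equivalent-sphere scale (πD³/6) so growth steps match the 10–30 mm chain
(2.42 / 3.99 / 5.96 ml for 15→20→25→30 mm).

Localization is summarised by the half-maximum centre of mass: quadrature-
weighted mean position of nodes carrying at least 50 % of the positive
peak. This ignores diffuse low-level background, and no localization claim
below one conductivity-mesh element (≈9 mm) is meaningful.

## What the synthetic study does and does not show

The generator emulates: layered head geometry with realistic 1 kHz tissue
contrasts, finite electrodes with contact impedance, pairwise injections
with far offsets, device-level additive noise, a growing blood inclusion at
two depths, and honest model mismatch via the two-mesh protocol and thin
unresolved CSF. It does not emulate: true anatomical geometry (gyri,
ventricles, skull thickness variation), electrode placement/contact
uncertainty, physiological drift, multi-frequency effects, or 3D at the
full study scale — the default experiments are 2D with 16 electrodes, so
passing tests demonstrate algorithmic correctness and the qualitative
ranking of the algorithms, not clinical performance. On this scaled study
the monitoring algorithm detects every simulated growth step of the
cortical chain down to 0.52 ml, and the diagonal (no-growth) scores stay
below zero; the absolute-imaging baseline only detects multi-ml changes,
with the linear-difference baseline in between — the same ordering the
full-scale anatomical study reports.

## Numerical choices and limitations

* Sparse LU for every CEM solve; dense algebra for the inversion-side
  normal equations and prior factors — the intended regime is ≲5·10³
  conductivity unknowns (the Γ_p assembly is dense N², the documented
  memory cliff).
* TV smoothing β = 10⁻³ throughout; positivity floor σ_min = 10⁻⁵ S/m in
  the library defaults, 10⁻³ S/m (physiological) in the experiment driver.
* γ₁ = 0.01 and gradient threshold 0.5·max for the edge indicator.
* Deterministic meshing, seeded noise and deterministic per-cell seed
  derivation make every experiment bit-reproducible.
* 3D phantoms (32 electrodes, EEG-cap-like layout: vertex plus three
  latitude rings) are built and tested geometrically; the reconstruction
  path is dimension-agnostic but the shipped experiment configurations are
  2D for runtime reasons.
* The Gauss–Newton iterations stop early (often ≤5 accepted steps) in the
  modeling-error-dominated regime; the first prior-conditioned steps carry
  essentially all of the δσ information, and the objective is monotone by
  construction.
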