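# eitmon — EIT-based bedside monitoring of intracerebral hemorrhage

Intracerebral hemorrhage (ICH) patients in intensive care need continuous
surveillance for hematoma expansion and secondary bleeds, but today the only
reliable check is a repeated CT scan. Electrical impedance tomography (EIT)
is a candidate bedside alternative: small currents are injected through
scalp electrodes, boundary voltages are recorded, and images of the brain's
electrical conductivity change are reconstructed — blood (≈0.70 S/m) is far
more conductive than white or gray matter (0.06–0.10 S/m), so a growing
bleed appears as a localized conductivity increase between two measurement
sessions.

`eitmon` is a simulation and reconstruction toolbox for this monitoring
problem, aimed at inverse-problems researchers. It provides:

* **Layered head phantoms** (2D disk / 3D sphere: scalp, skull, CSF, brain)
  with nested hemorrhage inclusions that grow over time, scalp electrodes
  and literature tissue conductivities at 1 kHz;
* a **complete electrode model (CEM) forward solver**: P1 finite elements
  for ∇·(σ∇u) = 0 with electrode boundary conditions
  u + z_ℓ σ ∂u/∂n = U_ℓ, ∫_{e_ℓ} σ ∂u/∂n dS = I_ℓ, and ΣI_ℓ = ΣU_ℓ = 0,
  plus the adjoint-based Jacobian ∂V/∂σ and noisy measurement simulation;
* three **reconstruction algorithms** for the conductivity change
  δσ = σ₂ − σ₁:
  * **TV** — generalized Tikhonov absolute imaging of each frame,
    `argmin ‖L_e(V − U(σ))‖² + α∫(‖∇σ‖² + β²)^½`, change by subtraction;
  * **LD** — one-step linear difference imaging,
    `(JᵀΓ_δe⁻¹J + Γ_p⁻¹)δσ = JᵀΓ_δe⁻¹δV`, with a distance-based Gaussian
    smoothness prior Γ_p(i,j) = std(σ)²exp(−‖xᵢ−xⱼ‖²/2a²);
  * **MO** — the monitoring algorithm: joint nonlinear estimation of
    (σ₁, δσ) with δσ supported on a brain region of interest
    (σ₂ = σ₁ + Kδσ), smoothed TV on δσ, parallel-level-sets weighted TV
    on σ₁ (tensor B(κ) = I − (1−γ)ν̂ν̂ᵀ built from a structural reference
    image), lagged Gauss–Newton with positivity, and a prior-conditioned
    LSQR (MLSQR) inner solver for the search direction;
* a **detectability experiment driver**: every ordered pair of hemorrhage
  states (D₁, D₂) is simulated and reconstructed; the integrals
  I = ∫δσ dx are normalized per algorithm/location, and the adjusted score
  `Q(D₁,D₂) = Ĩ(D₁,D₂) − max_k |Ĩ(D_k,D_k)|` subtracts the no-growth
  noise floor, so Q > 0 flags a change distinguishable from measurement
  noise. Heat maps and CSV tables are written per run.

## Worked example

`examples/02_reconstruct_growth.py` simulates a cortical bleed growing from
15 mm to 20 mm diameter (a 2.42 ml volume increase on the equivalent-sphere
scale) at the device noise level (0.067 % of the maximum healthy-frame
amplitude) and reconstructs δσ with all three algorithms:

```
TV (absolute + subtraction): integral -1.252e-06 S/m*m^2, positive blob 38.9 mm from the true centre
LD (linear difference)     : integral +5.574e-05 S/m*m^2, positive blob 30.8 mm from the true centre
MO (nonlinear ROI diff.)   : integral +4.932e-07 S/m*m^2, positive blob 2.4 mm from the true centre
```

A positive integral flags a growing conductive region; the blob distance
shows where the reconstruction puts it. For this small growth step only the
monitoring algorithm both signals the change and localizes it — the
reference algorithms' estimates are dominated by modeling-error artifacts,
which is exactly why nonlinear ROI difference imaging is attractive for
monitoring. `examples/03_detectability_grid.py` extends this to the full
scenario grid and prints the Q score per pair, ending with

```
smallest detected volume increase: 0.52 ml
```

for the monitoring algorithm on the cortical phantom.

There is also a thin CLI (`eitmon phantom | simulate | reconstruct |
detect`) driven by a TOML configuration, see `examples/run.toml`.

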