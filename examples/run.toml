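# Scaled-down monitoring study on the 2D layered head phantom.
# States are hemorrhage diameters in metres ("healthy" = no bleed).

[phantom]
dim = 2
n_electrodes = 16
h = 0.009
# outer radii of scalp, skull, CSF and brain (m)
layer_radii = [0.09, 0.085, 0.078, 0.076]
hemorrhage_diameters = [0.010, 0.015, 0.020, 0.025, 0.030]
location = "cortical"

[grid]
states = ["healthy", "0.010", "0.015", "0.020", "0.030"]
locations = ["cortical"]
algorithms = ["tv", "ld", "mo"]

[experiment]
master_seed = 1
sim_h = 0.004       # data-simulation mesh (inverse-crime guard: >=4x elements)
pot_h = 0.0065      # potential (FEM) mesh for the inversion
cond_h = 0.009      # conductivity (parameter) mesh
noise_rel = 6.7e-4  # 0.067 % of the healthy-frame maximum amplitude
mo_alpha_dsigma = 0.005
mo_alpha_sigma1 = 0.01
tv_alpha = 0.01
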