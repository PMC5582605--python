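# Three-vitamin study configuration: experimentally measured electronic
# properties serve as ground truths for the end-to-end recovery suite
# (`kdtli recover-all --config examples/vitamins.toml`).

seed = 1

[molecule.alpha_tocopherol]
name = "alpha-tocopherol"
sum_formula = "C29H50O2"
mass_amu = 430.7
alpha_opt_A3 = 58.0
sigma_abs_m2 = 0.0
alpha_stat_A3 = 54.0
mu_debye = 1.8
chi_A3 = 80.0
temperature_K = 400.0

[molecule.phylloquinone]
name = "phylloquinone"
sum_formula = "C31H46O2"
mass_amu = 450.7
alpha_opt_A3 = 52.0
sigma_abs_m2 = 0.0
alpha_stat_A3 = 58.0
mu_debye = 1.1
chi_A3 = 80.0
temperature_K = 450.0

[molecule.beta_carotene]
name = "beta-carotene"
sum_formula = "C40H56"
mass_amu = 536.9
alpha_opt_A3 = 83.0       # the interferometer measures the magnitude
sigma_abs_m2 = 0.0
alpha_stat_A3 = 211.0
mu_debye = 1.3
chi_A3 = 229.0
temperature_K = 460.0

[geometry]
grating_period_m = 266e-9
grating_separation_m = 0.105
slit_width_m = 110e-9
open_fraction_g3 = 0.41353383458646614
laser_wavelength_m = 532e-9
waist_x_m = 20e-6
waist_y_m = 920e-6

[laser]
power_W = 8.0
intensity_scale = 1.0

[electrode]
geometry_factor_K = 2.0e-3
gradient_coeff = 4.8e6
max_voltage_V = 10000.0

[beam]
mean_mps = 200.0
fwhm_fraction = 0.45
n_nodes = 41
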