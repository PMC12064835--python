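# Default parameters of the calvarial expansion model (versioned; see docs/methods.md).
#
# Calibration goals (in order): bone center ~3x stiffer than undifferentiated
# mesenchyme, ~1.5x more densely packed, an osteogenic front advancing
# ~15 um per 6 h, the velocity profile peaked at the front, the front
# outrunning individually tracked cells (~1.5x), and near-arrest of expansion
# when the bone center is excised.
E_m: 1.0            # kPa, stiffness of undifferentiated mesenchyme
E_o: 3.0            # kPa, stiffness of mature osteoblast (bone) tissue
rho0_m: 0.10        # cells/um, homeostatic mesenchyme density (1D-projected)
rho0_o: 0.15        # cells/um, homeostatic osteoblast density
eta: 10.0            # kPa*h, tissue viscosity
xi: 0.0058          # kPa*h/um^2, friction of mesenchyme with dermal/meningeal layers
xi_ratio: 9.5      # friction of matrix-rich bone relative to mesenchyme
                    # (osteoblasts anchored to their collagen meshwork;
                    # bone-center nuclei are nearly immobile in live imaging)
D: 1.7              # um^2/h, cell diffusion constant
tau: 0.95           # h, relaxation time of the net division rate
alpha: 0.28         # 1/h, maximal net growth/turnover rate: how fast the
                    # 1D-projected density relaxes toward homeostasis
                    # (includes out-of-plane accommodation of crowding)
beta: 0.24          # 1/h, differentiation-stiffness coupling (the fitted parameter)
r_col: 0.0032       # 1/h, collagen maturation rate; 1/r_col is the time for
                    # fresh osteoid to become the mature, stiff, anchored matrix
pi0: 280.0          # dimensionless amplitude of the growth pressure generated
                    # by active matrix deposition (fresh meshwork adds volume);
                    # the pressure scale is pi0*(E_o-E_m)*r_col*tau_P ~ 9 kPa
tau_P: 1.7          # h, viscoelastic relaxation time of the growth pressure
chi: 4.3            # dimensionless strain-mechanosensing gain: sensed
                    # stiffness E(col) + (E_o-E_m)*(chi*max(P_el,0)/E(col))^2
                    # drives differentiation; the quadratic strain stiffening
                    # of semiflexible collagen networks makes soft, poorly
                    # crosslinked matrix respond far more strongly
domain_length: 1000.0   # um, medial-lateral extent (+x = medial)
n_grid: 501         # grid points (2 um spacing)
dt: 0.1             # h, maximum explicit time step (clamped to stability bound)
t_end: 48.0         # h, simulated horizon
seed: 0             # seed for stochastic stages (tracers); the PDE is deterministic
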