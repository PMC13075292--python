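# Default ion parameters for the electromigration simulator.
# Literature limiting electrophoretic mobilities (m^2 V^-1 s^-1) and aqueous
# diffusion coefficients (m^2 s^-1) at 25 C; unit charge magnitude assumed.
# CV+ (crystal violet cation) is a bulky triarylmethane dye: its mobility and
# diffusivity are order-of-magnitude literature estimates.  All values are
# overridable in user configs.
"K+":      {charge_sign: 1,  mobility: 7.62e-8, diffusion_coeff: 1.96e-9}
"Na+":     {charge_sign: 1,  mobility: 5.19e-8, diffusion_coeff: 1.33e-9}
"CV+":     {charge_sign: 1,  mobility: 1.0e-8,  diffusion_coeff: 3.0e-10}
"Cl-":     {charge_sign: -1, mobility: 7.91e-8, diffusion_coeff: 2.03e-9}
"OH-":     {charge_sign: -1, mobility: 2.05e-7, diffusion_coeff: 5.27e-9}
"acetate": {charge_sign: -1, mobility: 4.24e-8, diffusion_coeff: 1.09e-9}
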