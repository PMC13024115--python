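# Tissue material/transport cards for the healthy and degenerated lumbar disc.
# Units: Em MPa; k0 in 1e-4 mm^4/(N s); cf0 mmol/L (signed fixed charge);
# phi0w water volume fraction.  AF entries given as [inner, outer] vary
# linearly across the twenty lamellae.  Degeneration = reduced fixed charge
# density of NP/AF plus reduced cartilage-endplate permeability (severe grade).
environment:
  c0: 150.0     # external bath concentration, mmol/L (0.15 M saline)
  T: 298.15     # K
  R: 8.314      # J/(mol K)

tissues:
  BEP:
    healthy:      {Em: 12000.0, nu: 0.3, beta_m: null, M: null, k0: 50000.0, phi0w: 0.6, cf0: 0.0, Phi: 1.0}
    degenerated:  {Em: 12000.0, nu: 0.3, beta_m: null, M: null, k0: 50000.0, phi0w: 0.6, cf0: 0.0, Phi: 1.0}
  CEP:
    healthy:      {Em: 0.25,  nu: 0.16, beta_m: 1.0,  M: 4.9, k0: 5.56, phi0w: 0.6, cf0: -326.0, Phi: 1.0}
    degenerated:  {Em: 0.328, nu: 0.25, beta_m: 1.06, M: 3.9, k0: 2.5,  phi0w: 0.6, cf0: -365.0, Phi: 1.0}
  NP:
    healthy:      {Em: 0.065, nu: 0.24, beta_m: 0.95, M: 1.9, k0: 5.5, phi0w: 0.8, cf0: -300.0, Phi: 1.0}
    degenerated:  {Em: 0.065, nu: 0.24, beta_m: 0.95, M: 1.9, k0: 5.5, phi0w: 0.8, cf0: -100.0, Phi: 1.0}
  AF:
    healthy:
      {Em: 0.027, nu: 0.16, beta_m: 0.09, M: 4.8,
       k0: [16.0, 47.0], phi0w: [0.8, 0.7], cf0: [-300.0, -100.0], Phi: 1.0}
    degenerated:
      {Em: 0.027, nu: 0.16, beta_m: 0.09, M: 4.8,
       k0: [16.0, 47.0], phi0w: [0.8, 0.7], cf0: [-150.0, -100.0], Phi: 1.0}

# Collagen (AO/AI/PO/PI), nanoscale elastic fibers (NEF, sf_II = 1 family),
# and the simplified directional moduli of the cartilage endplate
# (Ef_ap = Ef_l = 10 * Ef_a).
fibers:
  AO:  {Ef: 123.98, beta_f: 4.3,  I0: 1.04, sf_II: 1.0}
  AI:  {Ef: 52.85,  beta_f: 3.92, I0: 1.16, sf_II: 1.0}
  PO:  {Ef: 98.7,   beta_f: 3.82, I0: 1.21, sf_II: 1.0}
  PI:  {Ef: 20.17,  beta_f: 6.03, I0: 1.39, sf_II: 1.0}
  NEF: {Ef: 0.62,   beta_f: 2.68, I0: 1.93, sf_II: 1.0}
  # I0 = 1 degenerates the toe away: the simplified CEP fiber model is
  # linear in stretch with axial modulus Ef_a.
  CEP-axial: {Ef: 0.701, beta_f: 2.88, I0: 1.0, sf_II: 1.0,
              Ef_ap: 7.01, Ef_l: 7.01, Ef_a: 0.701}
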