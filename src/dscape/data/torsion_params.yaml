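# Torsional Fourier coefficients for the reduced disulfide models.
#
# Form per torsion type:  U(phi) = sum_n  0.5 * V_n * (1 + cos(n*phi - gamma_n))
# with n = 1..3, V_n in kJ/mol, gamma_n in degrees.  With gamma = (0, 180, 0)
# this reduces to the common OPLS convention
#   0.5*V1*(1+cos phi) + 0.5*V2*(1-cos 2phi) + 0.5*V3*(1+cos 3phi).
#
# These are OPLS-style effective parameters for a rigid-geometry torsional
# model (bond lengths/angles frozen, no solvent), chosen on physical grounds:
#   ccss:  C-C-S-S.  Near-degenerate trans (180 deg, 0.0 kJ/mol) and gauche
#          (+-60 deg, ~0.3 kJ/mol) minima; barriers 2.5-4.6 kJ/mol.  The two
#          gauche wells make open conformers entropically dominant at zero
#          force.
#   cssc:  C-S-S-C across the S-S bond.  Minima at +-90 deg; trans barrier
#          ~21.5 kJ/mol and cis barrier ~38.5 kJ/mol, the literature scale for
#          disulfide torsion.
#   cccs:  N/C-C(alpha)-C(beta)-S(gamma) side-chain path: threefold staggered
#          with mild trans preference.
#   backbone: generic soft threefold profile for the retained phi/psi-like
#          backbone torsions of the polypeptide path model.
ccss:
  v: [1.6, -1.2, 3.0]
  gamma: [0.0, 180.0, 0.0]
cssc:
  v: [17.0, -30.0, 0.0]
  gamma: [0.0, 180.0, 0.0]
cccs:
  v: [1.3, -0.2, 2.8]
  gamma: [0.0, 180.0, 0.0]
backbone:
  v: [0.8, -0.4, 1.8]
  gamma: [0.0, 180.0, 0.0]
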