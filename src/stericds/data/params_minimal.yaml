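# stericds builtin minimal parameter set, version 1.
#
# A deliberately small, pinned molecular-mechanics parameterization with
# UFF-like magnitudes: harmonic stretches and bends, cosine torsions,
# Lennard-Jones 12-6 van der Waals, Coulomb electrostatics, and a 10-12
# hydrogen-bond term.  Atom typing is by element only (no hybridization),
# which keeps the set total over the supported elements.  Wildcard entries
# ('*') provide fallbacks; a wildcard stretch with r0: null takes its rest
# length from the sum of covalent radii.
version: 1

nonbonded:
  cutoff: 12.0       # A, hard truncation
  dielectric: 1.5    # relative permittivity (vacuum-like simulations)
  scale14: 0.5       # 1-4 Lennard-Jones and Coulomb scaling

hbond:               # 10-12 donor-hydrogen...acceptor term
  epsilon: 2.0       # kcal/mol well depth
  r0: 1.9            # A, H...acceptor distance at the minimum
  cutoff: 5.0        # A

vdw:                 # epsilon kcal/mol, sigma A
  H:  {epsilon: 0.030, sigma: 2.42}
  C:  {epsilon: 0.086, sigma: 3.40}
  N:  {epsilon: 0.105, sigma: 3.26}
  O:  {epsilon: 0.105, sigma: 3.12}
  F:  {epsilon: 0.050, sigma: 2.97}
  P:  {epsilon: 0.200, sigma: 3.70}
  S:  {epsilon: 0.250, sigma: 3.56}
  Cl: {epsilon: 0.227, sigma: 3.47}
  Br: {epsilon: 0.251, sigma: 3.73}
  I:  {epsilon: 0.339, sigma: 4.01}

stretch:             # k kcal/mol/A^2, r0 A; keys are sorted element pairs
  C-C:  {k: 300.0, r0: 1.526}
  C-H:  {k: 340.0, r0: 1.090}
  C-N:  {k: 337.0, r0: 1.470}
  C-O:  {k: 320.0, r0: 1.410}
  C-F:  {k: 420.0, r0: 1.350}
  C-P:  {k: 220.0, r0: 1.840}
  C-S:  {k: 227.0, r0: 1.810}
  C-Cl: {k: 245.0, r0: 1.770}
  C-Br: {k: 220.0, r0: 1.940}
  H-N:  {k: 434.0, r0: 1.010}
  H-O:  {k: 553.0, r0: 0.960}
  H-S:  {k: 274.0, r0: 1.340}
  N-N:  {k: 300.0, r0: 1.400}
  N-O:  {k: 300.0, r0: 1.400}
  O-O:  {k: 300.0, r0: 1.460}
  O-P:  {k: 230.0, r0: 1.610}
  O-S:  {k: 240.0, r0: 1.580}
  S-S:  {k: 166.0, r0: 2.040}
  '*-*': {k: 280.0, r0: null}   # r0 from covalent radii

bend:                # k kcal/mol/rad^2, theta0 degrees; key A-center-B
  H-C-H:   {k: 35.0, theta0: 109.47}
  '*-C-*': {k: 50.0, theta0: 109.47}
  '*-N-*': {k: 50.0, theta0: 109.47}
  '*-O-*': {k: 55.0, theta0: 104.50}
  '*-S-*': {k: 62.0, theta0: 98.90}
  '*-P-*': {k: 45.0, theta0: 103.50}
  '*-*-*': {k: 50.0, theta0: 109.47}

torsion:             # E = v/2 (1 + cos(n*phi - gamma)); key around central bond
  '*-C-C-*': {v: 1.4, n: 3, gamma: 0.0}
  '*-C-O-*': {v: 1.0, n: 3, gamma: 0.0}
  '*-C-N-*': {v: 1.8, n: 3, gamma: 0.0}
  '*-C-S-*': {v: 1.0, n: 3, gamma: 0.0}
  '*-*-*-*': {v: 0.5, n: 3, gamma: 0.0}

charges:             # per-element default partial charge (e); structures that
  H: 0.0             # carry explicit charges override these
  C: 0.0
  N: 0.0
  O: 0.0
  F: 0.0
  P: 0.0
  S: 0.0
  Cl: 0.0
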