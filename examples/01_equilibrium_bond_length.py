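"""Where does the chain bond rest?

The bonded potential is a FENE spring (attractive, diverging at
R0 = 20 sigma) plus a WCA repulsive core. With the default parameters
(kappa = 30, R0 = 20) the two balance at 0.99 sigma: the chain behaves
like a string of touching beads that can nevertheless stretch enormously
before breaking.
"""

import numpy as np

import chromofold as cf

p = cf.ForceFieldParams()
r_eq = cf.equilibrium_bond_length(p)
print(f"equilibrium bond length: {r_eq:.6f} sigma (prints as {r_eq:.2f})")
print(f"bond energy there:       {cf.bonded_energy(r_eq, p):.4f} eps")
print(f"bond force there:        {cf.bonded_force(r_eq, p):+.2e} eps/sigma (zero at the minimum)")
for r in (0.9, 1.5, 10.0, 19.5):
    print(f"  r = {r:5.2f} sigma: U = {cf.bonded_energy(r, p):12.3f} eps, "
          f"F = {cf.bonded_force(r, p):+12.3f} eps/sigma")
print("The force is steeply repulsive below 1 sigma and increasingly "
      "attractive toward R0 = 20 sigma, where the FENE term diverges.")
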