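"""Build a hexagonal monolayer patch and exercise the DEC toolbox.

Constructs the primal/dual networks of a 19-cell patch, checks the exact
incidence identity B A = 0, evaluates the wedge-product area identity,
and verifies grad/div adjointness on a random field.
"""

import numpy as np

import monodec as md
from monodec.dec import Cochain

top, r = md.fixture_hexagonal_patch(2)
mono = md.Monolayer(top.cells, r)
g = mono.geometry

print(f"patch: {mono.n_cells} cells, {mono.n_edges} edges, "
      f"{mono.n_vertices} vertices; Euler characteristic "
      f"{mono.euler_characteristic} (disk: 1)")

prod = top.B @ top.A
print(f"max |B A| = {abs(prod).max() if prod.nnz else 0} (exactly 0: the "
      "boundary of a boundary is empty)")

# wedge-product area identity: (T_y ~^ T_x)_k / E_k = 6 at interior vertices
wedge = md.wedge_tilde(mono, Cochain("dual", 1, g.T[:, 1], 0),
                       Cochain("dual", 1, g.T[:, 0], 0))
iv = mono.reduced.retained_vertices
ratio = wedge.values[iv] / g.E_tri[iv]
print(f"wedge area ratio: {ratio.min():.12f} .. {ratio.max():.12f} "
      "(the chain-leg wedge of link components measures 6x triangle area)")

# adjointness [v, grad phi] = [(-div v)#, phi#]
rng = np.random.default_rng(0)
phi = np.zeros((mono.n_vertices, 2))
phi[iv] = rng.normal(size=(len(iv), 2))
v = np.zeros((mono.n_edges, 2))
re = mono.reduced.retained_edges
v[re] = rng.normal(size=(len(re), 2))
field = md.EdgeVectorField("edges", v)
lhs = md.inner_product(mono, field, md.grad(mono, phi))
rhs = md.inner_product(mono, md.neg_div(mono, field).values, phi)
print(f"adjointness: [v, grad phi] = {lhs:.12f}, "
      f"[(-div v)#, phi#] = {rhs:.12f} (equal: -div is the adjoint of grad)")
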