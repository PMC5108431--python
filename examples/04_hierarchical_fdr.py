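"""Two-level hierarchical FDR on a small made-up hypothesis tree.

Parents are the omnibus tests of two filter families; children are the
per-interaction tests inside each test-stage model.  With f=2 families and
d=4 child discoveries at q=0.1 the effective level is 0.1*(2+4)/(4+1)=0.12.
"""

import numpy as np

from spurgxe import effective_fdr_level, hierarchical_fdr

parents = [0.001, 0.004]                     # both omnibus tests significant
children = [
    np.array([0.002, 0.010, 0.300, 0.800]),  # marginal-filter interactions
    np.array([0.004, 0.030, 0.600, 0.900]),  # correlation-filter interactions
]
res = hierarchical_fdr(parents, children, q=0.1)

print(f"parent q-values: {np.round(res.parent_qvalues, 4)}")
for i, fam in enumerate(("marginal", "correlation")):
    print(f"{fam} child q-values: {np.round(res.child_qvalues[i], 4)} "
          f"rejected: {res.child_rejected[i]}")
print(f"child discoveries d={res.discoveries}, families f={res.n_families}")
print(f"effective level {res.effective_level:.3f} = "
      f"{effective_fdr_level(0.1, res.n_families, res.discoveries):.3f} "
      "(the cost of testing two families instead of one)")
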