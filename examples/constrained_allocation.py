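"""Constrained optimal allocation when extreme proportions are impractical.

If staffing makes it infeasible to give any sequence less than 15% or more
than 35% of the individuals, the optimum is sought inside that box.  For
weak correlation the solution sits exactly on the bounds.
"""

import numpy as np

from swalloc import DesignSpec, optimize_allocation

for rho in (0.2, 0.6):
    spec = DesignSpec(J=4, rho=rho, r=0.0)
    result = optimize_allocation(spec, lower=0.15, upper=0.35)
    print(f"rho={rho}: p* = {np.round(result.optimal_proportions, 4)}",
          f" active bounds: {result.active_bounds}")

print()
print("Reading: at rho=0.2 the unconstrained optimum would push the edge")
print("sequences above 0.35, so the constrained solution pins sequences 1 and")
print("4 to the upper bound and 2 and 3 to the lower; at rho=0.6 the")
print("unconstrained optimum is already inside the box and no bound is active.")
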